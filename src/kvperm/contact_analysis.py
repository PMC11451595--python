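"""Hydrophobic contact statistics between a bound ligand and S6 side chains.

A contact is an instance in which a carbon atom of one of the hydrophobic
S6 side chains (V409, P406, I405, I401, V398) lies within a cutoff
(default 4.5 Å) of any C or S atom of the ligand.  The headline statistic
is the number of *distinct subunits* contacted per residue per frame — a
wall binder at a subunit interface touches some side chains in one subunit
and others in two — while the raw atom-pair multiplicity is also recorded.
Hydrogens are excluded throughout (the scaffold and proxies are heavy-atom
only by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError
from .frames import FrameSet
from .pore_model import ROLE_S6, S6_RESIDUES, SUBUNITS, Scaffold

#: residues scored, in helix order
CONTACT_RESIDUES = ("V398", "I401", "I405", "P406", "V409")

#: ligand elements that count toward contacts (C/S heavy atoms)
LIGAND_ELEMENTS = ("C", "S")


@dataclass
class ContactTable:
    """Per-frame, per-residue subunit-contact sets."""

    table: pd.DataFrame  # columns: frame, time_ns, residue, subunits, n_subunits, n_pairs
    cutoff: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _ligand_atom_indices(frames: FrameSet) -> np.ndarray:
    mask = (frames.atoms["kind"] == "ligand") & frames.atoms["element"].isin(
        LIGAND_ELEMENTS
    )
    return np.flatnonzero(mask.to_numpy())


def _sidechain_atoms(scaffold: Scaffold):
    """Positions and (residue, subunit) labels of S6 side-chain carbons."""
    mask = scaffold.roles == ROLE_S6
    pos = scaffold.positions[mask]
    residues = np.array(
        [S6_RESIDUES[int(r)] for r in scaffold.resids[mask]], dtype=object
    )
    chains = scaffold.chains[mask]
    return pos, residues, chains


def find_contacts(
    ligand_pos: np.ndarray,
    sidechain_pos: np.ndarray,
    residues: np.ndarray,
    subunits: np.ndarray,
    cutoff: float = 4.5,
) -> dict[str, set[str]]:
    """Contacted subunits per residue in a single frame (exact criterion
    d <= cutoff, symmetric in atom order).  Neighbor search via a k-d tree.
    """
    if len(ligand_pos) == 0:
        raise InputError("empty ligand selection")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    tree = cKDTree(sidechain_pos)
    hits = tree.query_ball_point(ligand_pos, r=cutoff)
    out: dict[str, set[str]] = {res: set() for res in CONTACT_RESIDUES}
    for neighbor_list in hits:
        for j in neighbor_list:
            out[str(residues[j])].add(str(subunits[j]))
    return out


def contact_table(
    frames: FrameSet, scaffold: Scaffold, cutoff: float = 4.5
) -> ContactTable:
    """Evaluate the contact criterion over every frame of a trajectory."""
    lig_idx = _ligand_atom_indices(frames)
    if len(lig_idx) == 0:
        raise InputError("FrameSet contains no ligand C/S atoms")
    sc_pos, residues, chains = _sidechain_atoms(scaffold)
    if len(sc_pos) == 0:
        raise InputError("scaffold provides no s6_sidechain atoms")
    rows = []
    for f in range(frames.n_frames):
        lig = frames.positions[f, lig_idx, :]
        per_res = find_contacts(lig, sc_pos, residues, chains, cutoff)
        # atom-pair multiplicity (secondary statistic)
        d2 = ((lig[:, None, :] - sc_pos[None, :, :]) ** 2).sum(axis=2)
        within = d2 <= cutoff * cutoff
        for res in CONTACT_RESIDUES:
            subs = per_res[res]
            n_pairs = int(within[:, residues == res].sum())
            rows.append(
                (f, float(frames.times_ns[f]), res,
                 "".join(sorted(subs)), len(subs), n_pairs)
            )
    table = pd.DataFrame(
        rows,
        columns=["frame", "time_ns", "residue", "subunits", "n_subunits", "n_pairs"],
    )
    return ContactTable(table=table, cutoff=cutoff)


@dataclass
class ContactDistribution:
    """Percentage of frames at each subunit-contact count (0-4), per residue."""

    percent: pd.DataFrame  # index residues, columns 0..4, rows sum to 100
    modal: dict[str, int]

    def to_long(self) -> pd.DataFrame:
        long = self.percent.reset_index().melt(
            id_vars="residue", var_name="n_subunits", value_name="percent"
        )
        return long


def contact_distribution(table: ContactTable) -> ContactDistribution:
    """Summarize a ContactTable into the per-residue count distribution."""
    if len(table.table) == 0:
        raise InputError("contact table has no frames")
    counts = np.arange(len(SUBUNITS) + 1)
    rows = {}
    modal = {}
    for res in CONTACT_RESIDUES:
        sub = table.table.loc[table.table["residue"] == res, "n_subunits"]
        hist = np.array([(sub == c).sum() for c in counts], dtype=float)
        pct = 100.0 * hist / hist.sum()
        rows[res] = pct
        modal[res] = int(np.argmax(hist))
    percent = pd.DataFrame.from_dict(rows, orient="index", columns=counts)
    percent.index.name = "residue"
    return ContactDistribution(percent=percent, modal=modal)
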