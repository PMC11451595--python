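"""Time-ordered coordinate container shared by the generator and analyses.

A :class:`FrameSet` couples an (n_frames, n_atoms, 3) coordinate array in Å
with a per-atom metadata table (identity, kind, role, subunit) and a frame
time axis in ns.  Trajectories are written as multi-frame XYZ (plus plain
TSV sidecars for atom metadata and frame times) through MDAnalysis, so any
standard viewer can open them alongside the scaffold PDB topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

ATOM_COLUMNS = ["atom_id", "kind", "name", "element", "role", "chain"]


@dataclass
class FrameSet:
    """Coordinates for ions, ligand proxy atoms, and any extra markers."""

    times_ns: np.ndarray
    positions: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape[0] != len(self.times_ns):
            raise InputError("positions and times disagree on frame count")
        if self.positions.shape[1] != len(self.atoms):
            raise InputError("positions and atom table disagree on atom count")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InputError(f"atom table missing columns {missing}")

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def frame_interval_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times_ns[1] - self.times_ns[0])

    def indices(self, kind: str | None = None, name: str | None = None,
                role: str | None = None) -> np.ndarray:
        """Integer indices of atoms matching the given metadata filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if kind is not None:
            mask &= (self.atoms["kind"] == kind).to_numpy()
        if name is not None:
            mask &= (self.atoms["name"] == name).to_numpy()
        if role is not None:
            mask &= (self.atoms["role"] == role).to_numpy()
        return np.flatnonzero(mask)

    def coords(self, idx: np.ndarray) -> np.ndarray:
        """(n_frames, len(idx), 3) view of the selected atoms."""
        return self.positions[:, idx, :]

    # -- I/O ---------------------------------------------------------------

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write ``<prefix>.xyz``, ``<prefix>.atoms.tsv`` and ``<prefix>.times.tsv``."""
        import MDAnalysis as mda

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        xyz = prefix.with_suffix(".xyz")
        u = mda.Universe.empty(self.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", list(self.atoms["element"]))
        with mda.coordinates.XYZ.XYZWriter(str(xyz), n_atoms=self.n_atoms) as w:
            for f in range(self.n_frames):
                u.atoms.positions = self.positions[f]
                w.write(u.atoms)
        atoms_path = Path(str(prefix) + ".atoms.tsv")
        self.atoms.to_csv(atoms_path, sep="\t", index=False)
        times_path = Path(str(prefix) + ".times.tsv")
        pd.DataFrame({"frame": np.arange(self.n_frames),
                      "time_ns": self.times_ns}).to_csv(
            times_path, sep="\t", index=False)
        return {"xyz": xyz, "atoms": atoms_path, "times": times_path}

    @classmethod
    def read(cls, prefix: str | Path) -> "FrameSet":
        """Read a trajectory written by :meth:`write`."""
        import MDAnalysis as mda

        prefix = Path(prefix)
        for suffix in (".xyz", ".atoms.tsv", ".times.tsv"):
            candidate = (prefix.with_suffix(".xyz") if suffix == ".xyz"
                         else Path(str(prefix) + suffix))
            if not candidate.exists():
                raise InputError(f"trajectory sidecar not found: {candidate}")
        u = mda.Universe(str(prefix.with_suffix(".xyz")))
        pos = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        atoms = pd.read_csv(str(prefix) + ".atoms.tsv", sep="\t")
        times = pd.read_csv(str(prefix) + ".times.tsv", sep="\t")["time_ns"].to_numpy()
        return cls(times_ns=times, positions=pos.astype(float), atoms=atoms)

    @classmethod
    def from_universe(cls, universe, ion_selection: str = "name K",
                      ligand_selection: str | None = None,
                      frame_interval_ns: float | None = None) -> "FrameSet":
        """Build a FrameSet from any MDAnalysis universe (real trajectories).

        ``ion_selection``/``ligand_selection`` are MDAnalysis selection
        strings; atom identities come from the selection order.
        """
        groups: list[tuple[str, object]] = [("ion", universe.select_atoms(ion_selection))]
        if ligand_selection:
            groups.append(("ligand", universe.select_atoms(ligand_selection)))
        rows = []
        for kind, ag in groups:
            for i, atom in enumerate(ag):
                rows.append({
                    "atom_id": f"{kind}{i:04d}",
                    "kind": kind,
                    "name": str(atom.name),
                    "element": str(atom.name)[:1],
                    "role": "",
                    "chain": getattr(atom, "chainID", ""),
                })
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        n_sel = sum(len(ag) for _, ag in groups)
        pos = np.empty((len(universe.trajectory), n_sel, 3))
        times = np.empty(len(universe.trajectory))
        for f, ts in enumerate(universe.trajectory):
            pos[f] = np.concatenate([ag.positions for _, ag in groups], axis=0)
            times[f] = ts.time if frame_interval_ns is None else f * frame_interval_ns
        return cls(times_ns=times, positions=pos, atoms=atoms)
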