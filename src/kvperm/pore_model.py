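"""Pore geometry: axis, binding-site boundaries, and compartment assignment.

The frame of reference for every analysis in this package is the channel
pore axis, defined by the Cβ atoms of Y376 (extracellular anchor) and V409
(intracellular anchor) in the four subunits, and five reference oxygen
planes inside the selectivity filter (backbone carbonyls of Y376, G375,
V374, T373 and the T373 hydroxyl).  Positions are assigned to an ordered
vocabulary of compartments::

    EXT | S0 S1 S2 S3 S4 | SCAV CAVITY | GATE | CYTO

with z increasing from the cytoplasm toward the extracellular side.  K+
sites S0 (outermost) through S4 (innermost) lie between consecutive oxygen
planes; S_cav sits in the water-filled cavity just below the filter.

Boundary convention: axial intervals are half-open (lo, hi], so a position
exactly on an oxygen plane belongs to the more intracellular site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, InputError, StructuralInputError

# --------------------------------------------------------------------------
# Role vocabulary and compartment labels
# --------------------------------------------------------------------------

ROLE_AXIS_TOP = "axis_anchor_top"
ROLE_AXIS_BOTTOM = "axis_anchor_bottom"
ROLE_FILTER_PLANE = "filter_plane"
ROLE_GATE = "gate_marker"
ROLE_S6 = "s6_sidechain"
ROLE_LIGAND_C = "ligand_C"
ROLE_LIGAND_S = "ligand_S"
ROLE_LIGAND_N = "ligand_N"
ROLE_ION = "ion"

ROLES = (
    ROLE_AXIS_TOP,
    ROLE_AXIS_BOTTOM,
    ROLE_FILTER_PLANE,
    ROLE_GATE,
    ROLE_S6,
    ROLE_LIGAND_C,
    ROLE_LIGAND_S,
    ROLE_LIGAND_N,
    ROLE_ION,
)

#: Compartment labels, ordered extracellular -> intracellular.
LABELS = ("EXT", "S0", "S1", "S2", "S3", "S4", "SCAV", "CAVITY", "GATE", "CYTO")
FILTER_SITES = ("S0", "S1", "S2", "S3", "S4")
LABEL_CODE = {lab: i for i, lab in enumerate(LABELS)}

SUBUNITS = ("A", "B", "C", "D")

#: (resid, atom name) -> role, for the rat Kv2.1 numbering used throughout.
DEFAULT_ROLE_MAP: dict[tuple[int, str], str] = {
    (376, "CB"): ROLE_AXIS_TOP,
    (409, "CB"): ROLE_AXIS_BOTTOM,
    (376, "O"): ROLE_FILTER_PLANE,
    (375, "O"): ROLE_FILTER_PLANE,
    (374, "O"): ROLE_FILTER_PLANE,
    (373, "O"): ROLE_FILTER_PLANE,
    (373, "OG1"): ROLE_FILTER_PLANE,
    (408, "CA"): ROLE_GATE,
    (409, "CG1"): ROLE_S6,
    (406, "CG"): ROLE_S6,
    (405, "CD1"): ROLE_S6,
    (401, "CD1"): ROLE_S6,
    (398, "CG1"): ROLE_S6,
}

#: The five filter-plane groups in extracellular -> intracellular order.
PLANE_GROUPS: tuple[tuple[int, str], ...] = (
    (376, "O"),
    (375, "O"),
    (374, "O"),
    (373, "O"),
    (373, "OG1"),
)

#: S6 side chains scored in the hydrophobic-contact analysis.
S6_RESIDUES = {409: "V409", 406: "P406", 405: "I405", 401: "I401", 398: "V398"}


# --------------------------------------------------------------------------
# Scaffold
# --------------------------------------------------------------------------


@dataclass
class Scaffold:
    """Pseudo-protein anchor atoms with role and subunit metadata.

    All arrays have one entry per atom; ``positions`` is (n, 3) in Å.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    roles: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        for attr in ("names", "resnames", "resids", "chains", "roles"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        n = len(self.names)
        if not (
            len(self.resnames) == len(self.resids) == len(self.chains)
            == len(self.roles) == n and self.positions.shape == (n, 3)
        ):
            raise InputError("scaffold arrays have inconsistent lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(self, role: str) -> np.ndarray:
        """Positions of all atoms carrying ``role``."""
        return self.positions[self.roles == role]

    def group(self, resid: int, name: str) -> np.ndarray:
        mask = (self.resids == resid) & (self.names == name)
        return self.positions[mask]

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`StructuralInputError`."""
        for role, expected in (
            (ROLE_AXIS_TOP, 4),
            (ROLE_AXIS_BOTTOM, 4),
            (ROLE_GATE, 4),
        ):
            n = int(np.sum(self.roles == role))
            if n != expected:
                raise StructuralInputError(
                    f"scaffold must provide {expected} atoms with role "
                    f"'{role}', found {n}"
                )
        for resid, name in PLANE_GROUPS:
            if len(self.group(resid, name)) != 4:
                raise StructuralInputError(
                    f"filter plane {resid}:{name} must have 4 atoms "
                    f"(one per subunit)"
                )
        for role in (ROLE_AXIS_TOP, ROLE_AXIS_BOTTOM):
            chains = sorted(self.chains[self.roles == role])
            if chains != list(SUBUNITS):
                raise StructuralInputError(
                    f"role '{role}' must appear once in each of subunits "
                    f"{SUBUNITS}, found chains {chains}"
                )

    # -- PDB round trip ----------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        """Write the scaffold as a standard PDB file (chains A-D)."""
        import MDAnalysis as mda

        u = mda.Universe.empty(
            self.n_atoms,
            n_residues=self.n_atoms,
            atom_resindex=np.arange(self.n_atoms),
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(self.names))
        u.add_TopologyAttr("resnames", list(self.resnames))
        u.add_TopologyAttr("resids", list(self.resids))
        u.add_TopologyAttr("chainIDs", list(self.chains))
        u.add_TopologyAttr("segids", ["KV"])
        u.atoms.positions = self.positions
        u.atoms.write(str(path))

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        role_map: dict[tuple[int, str], str] | None = None,
    ) -> "Scaffold":
        """Read a PDB and infer roles from a (resid, atom name) mapping."""
        import MDAnalysis as mda

        role_map = DEFAULT_ROLE_MAP if role_map is None else role_map
        if not Path(path).exists():
            raise StructuralInputError(f"scaffold PDB not found: {path}")
        u = mda.Universe(str(path))
        ag = u.atoms
        roles = np.array(
            [
                role_map.get((int(r), str(n)), "")
                for r, n in zip(ag.resids, ag.names)
            ],
            dtype=object,
        )
        return cls(
            names=np.array(ag.names, dtype=object),
            resnames=np.array(ag.resnames, dtype=object),
            resids=np.array(ag.resids, dtype=int),
            chains=np.array(ag.chainIDs, dtype=object),
            roles=roles,
            positions=ag.positions.astype(float),
        )


# --------------------------------------------------------------------------
# PoreModel
# --------------------------------------------------------------------------


@dataclass
class PoreModel:
    """Axis plus site-boundary geometry of the pore.

    ``plane_z`` holds the signed axial offsets (Å along the axis from
    ``origin``) of the five filter oxygen planes, strictly decreasing from
    Y376:O down to T373:OG1.
    """

    origin: np.ndarray
    direction: np.ndarray  # unit vector, extracellular side positive
    plane_z: np.ndarray  # five offsets, decreasing
    z_gate: float
    z_scav: float
    s0_ceiling: float
    cylinder_diameter: float = 12.0
    lumen_radius: float = 8.0
    scav_half_width: float = 2.0
    scav_radius: float = 3.0
    gate_half_width: float = 2.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.plane_z = np.asarray(self.plane_z, dtype=float)
        if not np.all(np.diff(self.plane_z) < 0):
            raise GeometryError(
                "filter plane offsets must decrease from Y376:O to T373:OG1"
            )
        if not (self.plane_z[-1] > self.z_scav > self.z_gate):
            raise GeometryError("require z_T373OG1 > z_scav > z_gate")

    # -- derived geometry --------------------------------------------------

    @property
    def z_floor(self) -> float:
        """Lower edge of the GATE band; CYTO lies below."""
        return self.z_gate - self.gate_half_width

    @property
    def n_filter_sites(self) -> int:
        """S0 plus the four inter-plane sites: always 5 for a valid filter."""
        return len(self.plane_z)

    def boundary_table(self) -> list[tuple[float, float, str]]:
        """Half-open axial intervals (lo, hi] -> base label, covering the axis."""
        p = self.plane_z
        table = [
            (self.s0_ceiling, np.inf, "EXT"),
            (p[0], self.s0_ceiling, "S0"),
            (p[1], p[0], "S1"),
            (p[2], p[1], "S2"),
            (p[3], p[2], "S3"),
            (p[4], p[3], "S4"),
            (self.z_gate, p[4], "CAVITY"),
            (self.z_floor, self.z_gate, "GATE"),
            (-np.inf, self.z_floor, "CYTO"),
        ]
        return table

    def site_centers(self) -> dict[str, float]:
        """Representative axial coordinate for every compartment.

        Used by the synthetic coordinate emitter; each center maps back to
        its own label under :meth:`assign_site` (noiseless round trip).
        """
        p = self.plane_z
        return {
            "EXT": self.s0_ceiling + 5.0,
            "S0": 0.5 * (p[0] + self.s0_ceiling),
            "S1": 0.5 * (p[1] + p[0]),
            "S2": 0.5 * (p[2] + p[1]),
            "S3": 0.5 * (p[3] + p[2]),
            "S4": 0.5 * (p[4] + p[3]),
            "SCAV": self.z_scav,
            "CAVITY": 0.5 * (self.z_gate + (self.z_scav - self.scav_half_width)),
            "GATE": self.z_gate - 0.5 * self.gate_half_width,
            "CYTO": self.z_floor - 6.0,
        }

    # -- coordinate transforms ---------------------------------------------

    def axial_and_radial(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project positions onto the axis: (z along axis, r from axis), Å.

        Invariant under any rigid motion applied jointly to scaffold and
        positions.  Accepts a single 3-vector or an (n, 3) array.
        """
        pos = np.asarray(positions, dtype=float)
        single = pos.ndim == 1
        pos = np.atleast_2d(pos)
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite coordinates")
        rel = pos - self.origin
        z = rel @ self.direction
        perp = rel - np.outer(z, self.direction)
        r = np.linalg.norm(perp, axis=1)
        if single:
            return float(z[0]), float(r[0])
        return z, r

    def membrane_plane_coords(self, positions: np.ndarray) -> np.ndarray:
        """(x', y') coordinates in the plane orthogonal to the axis."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        d = self.direction
        # deterministic orthonormal basis completing the axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        rel = pos - self.origin
        return np.column_stack([rel @ e1, rel @ e2])

    # -- compartment assignment --------------------------------------------

    def assign_site(self, positions: np.ndarray) -> np.ndarray | str:
        """Compartment label(s) for 3D position(s).

        A position whose axial coordinate falls in a filter-site band but
        whose radial distance exceeds the analysis-cylinder radius is
        cavity-adjacent and labeled CAVITY; the SCAV label requires both
        axial proximity to the S_cav center and r < ``scav_radius``.
        """
        pos = np.asarray(positions, dtype=float)
        single = pos.ndim == 1
        z, r = self.axial_and_radial(pos)
        z = np.atleast_1d(z)
        r = np.atleast_1d(r)
        labels = self._assign_from_zr(z, r)
        if single:
            return str(labels[0])
        return labels

    def _assign_from_zr(self, z: np.ndarray, r: np.ndarray) -> np.ndarray:
        p = self.plane_z
        # ascending edges; interval k is (edges[k-1], edges[k]] -> label
        edges = np.array(
            [self.z_floor, self.z_gate, p[4], p[3], p[2], p[1], p[0], self.s0_ceiling]
        )
        by_band = np.array(
            ["CYTO", "GATE", "CAVITY", "S4", "S3", "S2", "S1", "S0", "EXT"],
            dtype=object,
        )
        # side='left': z exactly on an edge falls in the lower (intracellular) band
        idx = np.searchsorted(edges, z, side="left")
        labels = by_band[idx]
        in_filter = np.isin(labels, FILTER_SITES)
        labels[in_filter & (r > 0.5 * self.cylinder_diameter)] = "CAVITY"
        scav = (
            (labels == "CAVITY")
            & (np.abs(z - self.z_scav) <= self.scav_half_width)
            & (r < self.scav_radius)
        )
        labels[scav] = "SCAV"
        return labels

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "origin_A": self.origin.tolist(),
            "direction": self.direction.tolist(),
            "plane_z_A": self.plane_z.tolist(),
            "z_gate_A": self.z_gate,
            "z_scav_A": self.z_scav,
            "s0_ceiling_A": self.s0_ceiling,
            "cylinder_diameter_A": self.cylinder_diameter,
            "lumen_radius_A": self.lumen_radius,
            "scav_half_width_A": self.scav_half_width,
            "scav_radius_A": self.scav_radius,
            "gate_half_width_A": self.gate_half_width,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PoreModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        return cls(
            origin=np.array(doc["origin_A"]),
            direction=np.array(doc["direction"]),
            plane_z=np.array(doc["plane_z_A"]),
            z_gate=doc["z_gate_A"],
            z_scav=doc["z_scav_A"],
            s0_ceiling=doc["s0_ceiling_A"],
            cylinder_diameter=doc["cylinder_diameter_A"],
            lumen_radius=doc["lumen_radius_A"],
            scav_half_width=doc["scav_half_width_A"],
            scav_radius=doc["scav_radius_A"],
            gate_half_width=doc["gate_half_width_A"],
        )


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------


def build_pore_model(scaffold: Scaffold, **overrides) -> PoreModel:
    """Derive the pore frame of reference from scaffold anchor atoms.

    The axis runs through the centroids of the four V409:Cβ (bottom) and
    four Y376:Cβ (top) atoms, oriented intracellular -> extracellular;
    the origin is the midpoint of the two centroids.  Each filter plane
    offset is the mean axial projection of its four oxygens.  The S_cav
    center is placed midway between the T373:OG1 plane and the midpoint of
    (T373:OG1, gate); the S0 ceiling one mean inter-plane spacing above
    Y376:O.  Keyword overrides are forwarded to :class:`PoreModel`.
    """
    scaffold.validate()
    top = scaffold.select(ROLE_AXIS_TOP).mean(axis=0)
    bottom = scaffold.select(ROLE_AXIS_BOTTOM).mean(axis=0)
    span = top - bottom
    norm = np.linalg.norm(span)
    if norm < 1e-6:
        raise GeometryError("axis anchor centroids coincide; axis undefined")
    direction = span / norm
    origin = 0.5 * (top + bottom)

    def proj(points: np.ndarray) -> float:
        return float(np.mean((points - origin) @ direction))

    plane_z = np.array([proj(scaffold.group(r, n)) for r, n in PLANE_GROUPS])
    if not np.all(np.diff(plane_z) < 0):
        raise GeometryError(
            "filter planes are not ordered Y376:O > G375:O > V374:O > "
            "T373:O > T373:OG1 along the axis"
        )
    z_gate = proj(scaffold.select(ROLE_GATE))
    z5 = plane_z[-1]
    cavity_mid = 0.5 * (z5 + z_gate)
    z_scav = 0.5 * (z5 + cavity_mid)
    spacing = float(np.mean(-np.diff(plane_z)))
    s0_ceiling = plane_z[0] + spacing
    return PoreModel(
        origin=origin,
        direction=direction,
        plane_z=plane_z,
        z_gate=z_gate,
        z_scav=z_scav,
        s0_ceiling=s0_ceiling,
        **overrides,
    )
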