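"""Engine-agnostic restraint potentials and voltage/field utilities.

Evaluators for the three bias/confinement potentials used when simulating
the activated channel and its inhibitor complexes:

* a weak structural dihedral bias toward reference (experimental) angles,
  a six-term cosine series with factorial weights,
      U(θ) = k Σ_{m=1..6} (1 − cos mΔ) / m!,   Δ = θ − θ_ref,
  zero and stationary at the reference, 360°-periodic, default k = 1 k_BT;
* flat-bottom confinements, zero inside a tolerance d0 and harmonic
  0.5 k (d − d0)² beyond it, applied either radially about the pore axis
  (d0 = 10 Å, k = 100 kcal/mol/Å²) or axially about the V409:Cβ center
  (d0 = 15 Å);
* a knock-on pulling restraint toward the Y376/G375 carbonyl oxygens
  (target ≈ 3 Å, k = 3 kcal/mol/Å²).

The constant-field voltage conversion is computed from physical constants:
1 kcal·mol⁻¹·Å⁻¹·e⁻¹ ≈ 43.4 mV/Å.

The printed source of the dihedral series is ambiguous about a (−1)^m
factor; the default reading here is the unique non-negative form whose
minimum is at the reference structure (required of a potential that favors
it).  The literal alternating form is selectable via ``convention``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import constants

from .errors import InputError
from .pore_model import ROLE_AXIS_BOTTOM, ROLE_AXIS_TOP, Scaffold

_FACTORIALS = np.array([math.factorial(m) for m in range(1, 7)], dtype=float)
_M = np.arange(1, 7, dtype=float)


def kBT_kcal_per_mol(temperature_K: float = 298.0) -> float:
    """Thermal energy k_B·T in kcal/mol, from CODATA constants."""
    return constants.k * temperature_K * constants.N_A / (constants.calorie * 1e3)


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


def _wrap_deg(angle):
    """Wrap angle(s) to the principal interval [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class DihedralBiasSpec:
    """Cosine-series bias toward reference dihedral angles (φ, ψ, χ1)."""

    theta_ref_deg: float
    k: float = field(default_factory=kBT_kcal_per_mol)  # kcal/mol
    order: int = 6
    convention: str = "favor-reference"  # or "literal"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise InputError("force constant must be >= 0")
        if self.convention not in ("favor-reference", "literal"):
            raise InputError(f"unknown convention {self.convention!r}")
        self.theta_ref_deg = float(_wrap_deg(self.theta_ref_deg))


@dataclass
class FlatBottomSpec:
    """Zero inside d0, harmonic outside; radial about the pore axis or
    axial about the V409:Cβ center."""

    kind: str  # "radial-about-axis" | "axial-about-point"
    d0: float = 10.0  # Å
    k: float = 100.0  # kcal/mol/Å^2

    def __post_init__(self) -> None:
        if self.kind not in ("radial-about-axis", "axial-about-point"):
            raise InputError(f"unknown flat-bottom kind {self.kind!r}")
        if self.d0 <= 0 or self.k <= 0:
            raise InputError("flat-bottom requires d0 > 0 and k > 0")


@dataclass
class KnockOnPullSpec:
    """Harmonic pull of the central filter ion toward the Y376/G375
    carbonyl oxygens in the four subunits."""

    target_distance: float = 3.0  # Å
    k: float = 3.0  # kcal/mol/Å^2
    activation_time_ns: float = 100.0
    target_atoms: tuple = (("Y376", "O"), ("G375", "O"))

    def __post_init__(self) -> None:
        if self.target_distance <= 0 or self.k <= 0:
            raise InputError("pull requires positive target distance and k")


# --------------------------------------------------------------------------
# Energy evaluations
# --------------------------------------------------------------------------


def dihedral_bias_energy(theta_deg, spec: DihedralBiasSpec):
    """Bias energy U(θ); same units as spec.k.  Vectorized over θ."""
    delta = np.radians(_wrap_deg(np.asarray(theta_deg, dtype=float) - spec.theta_ref_deg))
    terms = (1.0 - np.cos(np.multiply.outer(delta, _M))) / _FACTORIALS
    if spec.convention == "literal":
        terms = terms * ((-1.0) ** _M)
    u = spec.k * terms.sum(axis=-1)
    return float(u) if np.isscalar(theta_deg) else u


def dihedral_bias_gradient(theta_deg, spec: DihedralBiasSpec):
    """dU/dθ in (energy)/degree, for stationarity checks and engines."""
    delta = np.radians(_wrap_deg(np.asarray(theta_deg, dtype=float) - spec.theta_ref_deg))
    terms = _M * np.sin(np.multiply.outer(delta, _M)) / _FACTORIALS
    if spec.convention == "literal":
        terms = terms * ((-1.0) ** _M)
    g = spec.k * terms.sum(axis=-1) * math.pi / 180.0
    return float(g) if np.isscalar(theta_deg) else g


def flat_bottom_energy(d, spec: FlatBottomSpec):
    """(energy, force magnitude) of the flat-bottom confinement at d.

    Energy is 0 for d <= d0 and 0.5 k (d − d0)² beyond; both the energy
    and its derivative are continuous at d0.  Force = |dU/dd|.
    """
    d = np.asarray(d, dtype=float)
    excess = np.maximum(d - spec.d0, 0.0)
    u = 0.5 * spec.k * excess**2
    f = spec.k * excess
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def restraint_distance(position, spec: FlatBottomSpec, scaffold: Scaffold) -> float:
    """The collective variable the confinement acts on, from scaffold anchors.

    Radial kind: perpendicular distance to the pore axis (Y376:Cβ /
    V409:Cβ centroids).  Axial kind: |projection onto the axis| measured
    from the V409:Cβ center.
    """
    top = scaffold.select(ROLE_AXIS_TOP)
    bottom = scaffold.select(ROLE_AXIS_BOTTOM)
    if len(top) == 0 or len(bottom) == 0:
        raise InputError("scaffold lacks the axis anchor atoms")
    top_c = top.mean(axis=0)
    bot_c = bottom.mean(axis=0)
    axis = top_c - bot_c
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise InputError("degenerate axis anchors")
    axis /= norm
    pos = np.asarray(position, dtype=float)
    if spec.kind == "radial-about-axis":
        rel = pos - 0.5 * (top_c + bot_c)
        return float(np.linalg.norm(rel - (rel @ axis) * axis))
    rel = pos - bot_c
    return float(abs(rel @ axis))


# --------------------------------------------------------------------------
# Voltage / field conversion
# --------------------------------------------------------------------------


def unit_constant() -> float:
    """mV/Å corresponding to a field of 1 kcal·mol⁻¹·Å⁻¹·e⁻¹ (≈ 43.4)."""
    kcal_per_mol_J = constants.calorie * 1e3 / constants.N_A
    volts_per_A = kcal_per_mol_J / constants.e
    return volts_per_A * 1e3


def voltage_field_conversion(voltage_mV: float, box_length_A: float) -> float:
    """Constant electric field (kcal·mol⁻¹·Å⁻¹·e⁻¹) producing the given
    transmembrane voltage across a box of the given length."""
    if box_length_A <= 0:
        raise ValueError("box length must be positive")
    return (voltage_mV / box_length_A) / unit_constant()


# --------------------------------------------------------------------------
# Export / import
# --------------------------------------------------------------------------

_SPEC_KINDS = {
    "dihedral_bias": DihedralBiasSpec,
    "flat_bottom": FlatBottomSpec,
    "knockon_pull": KnockOnPullSpec,
}


def reference_restraint_set() -> list:
    """The full restraint set of the simulation protocol: structural
    dihedral bias, radial and axial inhibitor confinements, knock-on pull."""
    return [
        DihedralBiasSpec(theta_ref_deg=0.0),
        FlatBottomSpec(kind="radial-about-axis", d0=10.0, k=100.0),
        FlatBottomSpec(kind="axial-about-point", d0=15.0, k=100.0),
        KnockOnPullSpec(),
    ]


def export_restraints(specs, path: str | Path | None = None) -> str:
    """Serialize restraint specs to a JSON document with explicit units."""
    entries = []
    for spec in specs:
        if isinstance(spec, DihedralBiasSpec):
            entries.append({
                "type": "dihedral_bias",
                "k_kcal_per_mol": spec.k,
                "theta_ref_deg": spec.theta_ref_deg,
                "order": spec.order,
                "convention": spec.convention,
            })
        elif isinstance(spec, FlatBottomSpec):
            entries.append({
                "type": "flat_bottom",
                "kind": spec.kind,
                "d0_A": spec.d0,
                "k_kcal_per_mol_A2": spec.k,
                "anchors": "Y376:CB/V409:CB axis" if spec.kind == "radial-about-axis"
                           else "V409:CB center",
            })
        elif isinstance(spec, KnockOnPullSpec):
            entries.append({
                "type": "knockon_pull",
                "target_distance_A": spec.target_distance,
                "k_kcal_per_mol_A2": spec.k,
                "activation_time_ns": spec.activation_time_ns,
                "target_atoms": [list(t) for t in spec.target_atoms],
            })
        else:
            raise InputError(f"cannot export restraint of type {type(spec).__name__}")
    text = json.dumps({"restraints": entries}, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def import_restraints(source: str | Path) -> list:
    """Read back a document written by :func:`export_restraints`."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = json.loads(text)
    specs = []
    for entry in doc["restraints"]:
        kind = entry["type"]
        if kind == "dihedral_bias":
            specs.append(DihedralBiasSpec(
                theta_ref_deg=entry["theta_ref_deg"],
                k=entry["k_kcal_per_mol"],
                order=entry["order"],
                convention=entry["convention"],
            ))
        elif kind == "flat_bottom":
            specs.append(FlatBottomSpec(
                kind=entry["kind"], d0=entry["d0_A"], k=entry["k_kcal_per_mol_A2"],
            ))
        elif kind == "knockon_pull":
            specs.append(KnockOnPullSpec(
                target_distance=entry["target_distance_A"],
                k=entry["k_kcal_per_mol_A2"],
                activation_time_ns=entry["activation_time_ns"],
                target_atoms=tuple(tuple(t) for t in entry["target_atoms"]),
            ))
        else:
            raise InputError(f"unknown restraint type {kind!r}")
    return specs
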