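"""Synthetic knock-on trajectories for an activated K+ channel.

Multi-microsecond permeation trajectories of Kv2.1 are not reproducible at
desk scale, so this module generates surrogates with the statistical
structure the analyses assume: a continuous-time stochastic automaton over
pore compartments (Gillespie sampling, exponential waiting times) coupled
to a coordinate emitter that realizes compartment states as noisy 3D
positions on a four-fold symmetric pseudo-protein scaffold.

The automaton encodes the knock-on cycle: three K+ ions occupy the
selectivity filter (canonical slots S1/S3/S4); a fourth ion loading into
S_cav from the cytoplasm creates a short-lived 4-ion configuration that
resolves either by the incoming ion returning (rate ``k_return``) or by
ejection of the outermost filter ion into the extracellular space (rate
``k_eject``, voltage-boosted), upon which the remaining file and the S_cav
ion advance concertedly.  Four iterations of the cycle carry a tagged ion
all the way across.  A mirrored pathway (extracellular entry at S0,
inward ejection through S_cav) makes the net flux vanish at 0 mV.

Inhibitor modes:

* ``TEA``   -- the blocker binds on-axis at a site just below S_cav; while
  bound, cytoplasmic loading is abolished.  Binding requires an applied
  voltage (field-driven entry of the cation); unbinding occurs only at
  0 mV, where the site is no longer absorbing.
* ``RY785`` -- the inhibitor sits off-axis against the S6 side chains of
  one subunit interface; cytoplasmic entry rates are divided by
  ``ry785_attenuation`` (default 4) but permeation is not abolished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, InternalConsistencyError
from .frames import ATOM_COLUMNS, FrameSet
from .pore_model import (
    ROLE_AXIS_BOTTOM,
    ROLE_AXIS_TOP,
    ROLE_FILTER_PLANE,
    ROLE_GATE,
    ROLE_S6,
    SUBUNITS,
    PoreModel,
    Scaffold,
)

# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

#: Reference permeation statistics the defaults are calibrated to:
#: 45 outward events in 24.5 us of driven simulation at 100 mV.
TARGET_MEAN_INTERVAL_US = 24.5 / 45.0

_K_RETURN_DEFAULT = 180.0  # per us; the loaded ion "often returns"
_K_EJECT_DEFAULT = 12.0  # per us, before the voltage boost


def calibrate_k_enter(
    k_return_per_us: float = _K_RETURN_DEFAULT,
    k_eject_per_us: float = _K_EJECT_DEFAULT,
    voltage_mV: float = 100.0,
    v0_mV: float = 50.0,
    target_interval_us: float = TARGET_MEAN_INTERVAL_US,
) -> float:
    """Base cytoplasmic entry rate (per us) that yields the target interval.

    For the renewal structure of the automaton the mean time per outward
    ejection is ``(1/p_e) * (1/k_enter_eff + 1/k_res)`` with
    ``k_res = k_eject*boost + k_return`` and ``p_e`` the ejection branching
    probability; inverting for ``k_enter`` gives the calibration in closed
    form.
    """
    boost = math.exp(voltage_mV / v0_mV)
    ke_eff = k_eject_per_us * boost
    k_res = ke_eff + k_return_per_us
    p_e = ke_eff / k_res
    inv_enter_eff = target_interval_us * p_e - 1.0 / k_res
    if inv_enter_eff <= 0:
        raise ConfigError("target interval unreachable with these branch rates")
    return (1.0 / inv_enter_eff) / boost


@dataclass
class GeneratorParams:
    """Rates, voltage, inhibitor mode and noise scales for the automaton.

    All rates are in events per microsecond; the seed is mandatory and is
    the only source of randomness.
    """

    seed: int
    duration_us: float = 24.5
    frame_interval_ns: float = 1.0
    voltage_mV: float = 100.0
    v0_mV: float = 50.0
    k_enter_per_us: float = field(default_factory=calibrate_k_enter)
    k_return_per_us: float = _K_RETURN_DEFAULT
    k_eject_per_us: float = _K_EJECT_DEFAULT
    k_reload_per_us: float = 280.0  # entry into an induced S4 vacancy
    mode: str = "none"  # none | TEA | RY785
    tea_bind_per_us: float = 200.0
    tea_unbind_per_us: float = 2.0  # active only at 0 mV
    ry785_attenuation: float = 4.0
    sigma_z_A: float = 0.5
    sigma_xy_A: float = 0.5
    tea_sigma_A: float = 0.8
    ry785_r0_A: float = 6.0
    ry785_interface_angle_deg: float = 45.0
    ligand_jitter_A: float = 0.25
    force_eject: bool = False  # deterministic branching: ejection always wins
    tea_initially_bound: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in (
            "k_enter_per_us", "k_return_per_us", "k_eject_per_us",
            "k_reload_per_us", "tea_bind_per_us", "tea_unbind_per_us",
            "sigma_z_A", "sigma_xy_A", "tea_sigma_A", "ligand_jitter_A",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ry785_attenuation < 1:
            raise ConfigError("ry785_attenuation must be >= 1")
        if self.duration_us <= 0:
            raise ConfigError("duration_us must be positive")
        if self.frame_interval_ns <= 0 or self.frame_interval_ns > self.duration_us * 1e3:
            raise ConfigError("frame interval must be positive and <= duration")
        if self.mode not in ("none", "TEA", "RY785"):
            raise ConfigError(f"unknown inhibitor mode {self.mode!r}")

    @classmethod
    def for_mode(cls, mode: str, seed: int, **overrides) -> "GeneratorParams":
        """Defaults mirroring the study designs: 24.5 us uninhibited,
        5 us TEA, 5.5 us RY785."""
        durations = {"none": 24.5, "TEA": 5.0, "RY785": 5.5}
        if mode not in durations:
            raise ConfigError(f"unknown inhibitor mode {mode!r}")
        kwargs = {"duration_us": durations[mode], "mode": mode}
        kwargs.update(overrides)
        return cls(seed=seed, **kwargs)


# --------------------------------------------------------------------------
# Event log
# --------------------------------------------------------------------------

EVENT_TYPES = (
    "load", "return", "eject", "shift",
    "bind_inhibitor", "unbind_inhibitor", "induced_pull",
)

#: Canonical single-file order of compartments, intracellular -> extracellular,
#: used by the no-passing invariant check.
_FILE_ORDER = {"CYTO": 0, "SCAV": 1, "S4": 2, "S3": 3, "S1": 4, "S0": 5, "EXT": 6}


@dataclass
class Event:
    time_ns: float
    event: str
    ion: str
    src: str
    dst: str


@dataclass
class EventLog:
    """Ordered record of every compartment transition in a generated run."""

    records: list[Event]
    initial: dict[str, str]  # ion/ligand id -> compartment at t = 0
    duration_ns: float
    voltage_mV: float
    mode: str

    @property
    def eject_count(self) -> int:
        """Outward ejections (= complete outward permeation events)."""
        return sum(1 for r in self.records if r.event == "eject" and r.dst == "EXT")

    @property
    def inward_count(self) -> int:
        return sum(1 for r in self.records if r.event == "eject" and r.dst == "CYTO")

    def ions(self) -> list[str]:
        seen = [i for i in self.initial if not i.startswith("TEA")]
        for r in self.records:
            if r.ion not in seen and not r.ion.startswith("TEA"):
                seen.append(r.ion)
        return seen

    def timelines(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        """Exact per-ion occupancy series: (transition times ns, labels).

        The first entry of each series is the ion's compartment at t = 0.
        """
        out: dict[str, tuple[list[float], list[str]]] = {
            ion: ([0.0], [self.initial.get(ion, "CYTO")]) for ion in self.ions()
        }
        for r in self.records:
            if r.ion.startswith("TEA"):
                continue
            times, labs = out.setdefault(r.ion, ([0.0], ["CYTO"]))
            if labs[-1] != r.src:
                raise InternalConsistencyError(
                    f"ion {r.ion} moves from {r.src} but is at {labs[-1]}"
                )
            times.append(r.time_ns)
            labs.append(r.dst)
        return {
            ion: (np.asarray(t), labs) for ion, (t, labs) in out.items()
        }

    def tea_bound_intervals(self) -> list[tuple[float, float]]:
        """Time intervals (ns) during which the TEA blocker is bound."""
        intervals = []
        bound_since = 0.0 if self.initial.get("TEA") == "BOUND" else None
        for r in self.records:
            if r.event == "bind_inhibitor":
                bound_since = r.time_ns
            elif r.event == "unbind_inhibitor" and bound_since is not None:
                intervals.append((bound_since, r.time_ns))
                bound_since = None
        if bound_since is not None:
            intervals.append((bound_since, self.duration_ns))
        return intervals

    def validate(self) -> None:
        """Replay the log and check conservation, exclusivity and no-passing."""
        t_prev = 0.0
        state = {
            ion: comp for ion, comp in self.initial.items()
            if not ion.startswith("TEA")
        }
        for r in self.records:
            if r.time_ns < t_prev - 1e-9:
                raise InternalConsistencyError("event times decrease")
            t_prev = r.time_ns
            if r.event in ("bind_inhibitor", "unbind_inhibitor"):
                continue
            if r.event not in EVENT_TYPES:
                raise InternalConsistencyError(f"unknown event {r.event!r}")
            current = state.get(r.ion, "CYTO")
            if current != r.src:
                raise InternalConsistencyError(
                    f"ion {r.ion} recorded leaving {r.src} while at {current}"
                )
            if r.dst not in ("CYTO", "EXT") and r.dst in state.values():
                occupant = [i for i, c in state.items() if c == r.dst]
                raise InternalConsistencyError(
                    f"site {r.dst} already holds {occupant}"
                )
            state[r.ion] = r.dst
            self._check_single_file(state)

    @staticmethod
    def _check_single_file(state: dict[str, str]) -> None:
        # within the pore, ions keep their file order by construction;
        # verify no site holds two ions (EXT/CYTO are reservoirs)
        pore = [c for c in state.values() if c in _FILE_ORDER and c not in ("CYTO", "EXT")]
        if len(pore) != len(set(pore)):
            raise InternalConsistencyError("two ions share one pore site")

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time_ns, r.event, r.ion, r.src, r.dst) for r in self.records],
            columns=["time_ns", "event", "ion", "src", "dst"],
        )

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Stochastic simulation
# --------------------------------------------------------------------------


class _AutomatonState:
    """Mutable state of the knock-on automaton during a run."""

    def __init__(self, params: GeneratorParams, initial: dict[str, str]):
        self.filter: dict[str, str | None] = {
            "S1": "K0001", "S3": "K0002", "S4": "K0003", "S0": None,
        }
        self.scav: str | None = None
        self.tea_bound = params.mode == "TEA" and params.tea_initially_bound
        self.next_k = 4
        self.next_e = 1
        self.cyto_pool: list[str] = []
        self.ext_pool: list[str] = []
        self.initial = initial  # ion -> compartment at t = 0

    def fresh_cyto(self) -> str:
        if self.cyto_pool:
            return self.cyto_pool.pop()
        ion = f"K{self.next_k:04d}"
        self.next_k += 1
        self.initial[ion] = "CYTO"
        return ion

    def fresh_ext(self) -> str:
        if self.ext_pool:
            return self.ext_pool.pop()
        ion = f"E{self.next_e:04d}"
        self.next_e += 1
        self.initial[ion] = "EXT"
        return ion


def simulate_knockon(params: GeneratorParams) -> EventLog:
    """Run the knock-on automaton; returns the complete event log.

    The log *is* the exact occupancy series (see
    :meth:`EventLog.timelines`); frame-sampled coordinates are produced
    separately by :func:`emit_coordinates`.  Reproducible bit-for-bit for a
    fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    duration_ns = params.duration_us * 1e3
    boost = math.exp(params.voltage_mV / params.v0_mV)
    down = math.exp(-params.voltage_mV / params.v0_mV)
    atten = params.ry785_attenuation if params.mode == "RY785" else 1.0
    per_ns = 1e-3

    records: list[Event] = []
    initial = {"K0001": "S1", "K0002": "S3", "K0003": "S4"}
    st = _AutomatonState(params, initial)
    if params.mode == "TEA":
        initial["TEA"] = "BOUND" if st.tea_bound else "CYTO"

    t = 0.0
    while True:
        channels: list[tuple[float, str]] = []
        pore_free = st.scav is None and st.filter["S0"] is None
        if params.mode == "TEA" and not st.tea_bound and params.voltage_mV > 0 and pore_free:
            channels.append((params.tea_bind_per_us * per_ns, "tea_bind"))
        if st.tea_bound and params.voltage_mV == 0:
            channels.append((params.tea_unbind_per_us * per_ns, "tea_unbind"))
        if pore_free and not st.tea_bound:
            channels.append((params.k_enter_per_us * boost / atten * per_ns, "load"))
            channels.append((params.k_enter_per_us * down * per_ns, "top_entry"))
        if st.scav is not None:
            if not params.force_eject:
                channels.append((params.k_return_per_us * per_ns, "return"))
            channels.append((params.k_eject_per_us * boost * per_ns, "eject"))
        if st.filter["S0"] is not None:
            channels.append((params.k_return_per_us * per_ns, "s0_return"))
            if not st.tea_bound:
                channels.append((params.k_eject_per_us * down / atten * per_ns, "inward_eject"))

        total = sum(rate for rate, _ in channels)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > duration_ns:
            break
        u = rng.random() * total
        acc = 0.0
        chosen = channels[-1][1]
        for rate, name in channels:
            acc += rate
            if u <= acc:
                chosen = name
                break

        if chosen == "tea_bind":
            st.tea_bound = True
            records.append(Event(t, "bind_inhibitor", "TEA", "CYTO", "SCAV"))
        elif chosen == "tea_unbind":
            st.tea_bound = False
            records.append(Event(t, "unbind_inhibitor", "TEA", "SCAV", "CYTO"))
        elif chosen == "load":
            ion = st.fresh_cyto()
            st.scav = ion
            records.append(Event(t, "load", ion, "CYTO", "SCAV"))
        elif chosen == "return":
            records.append(Event(t, "return", st.scav, "SCAV", "CYTO"))
            st.cyto_pool.append(st.scav)
            st.scav = None
        elif chosen == "eject":
            _concerted_outward(st, records, t)
        elif chosen == "top_entry":
            ion = st.fresh_ext()
            st.filter["S0"] = ion
            records.append(Event(t, "load", ion, "EXT", "S0"))
        elif chosen == "s0_return":
            records.append(Event(t, "return", st.filter["S0"], "S0", "EXT"))
            st.ext_pool.append(st.filter["S0"])
            st.filter["S0"] = None
        elif chosen == "inward_eject":
            _concerted_inward(st, records, t)

    log = EventLog(
        records=records,
        initial=initial,
        duration_ns=duration_ns,
        voltage_mV=params.voltage_mV,
        mode=params.mode,
    )
    log.validate()
    return log


def _concerted_outward(st: _AutomatonState, records: list[Event], t: float) -> None:
    """Eject the outermost ion; advance the file and the S_cav ion."""
    out, s3, s4, scav = st.filter["S1"], st.filter["S3"], st.filter["S4"], st.scav
    records.append(Event(t, "eject", out, "S1", "EXT"))
    records.append(Event(t, "shift", s3, "S3", "S1"))
    records.append(Event(t, "shift", s4, "S4", "S3"))
    records.append(Event(t, "shift", scav, "SCAV", "S4"))
    st.filter.update({"S1": s3, "S3": s4, "S4": scav})
    st.scav = None
    st.ext_pool.append(out)


def _concerted_inward(st: _AutomatonState, records: list[Event], t: float) -> None:
    """Mirror pathway: the S0 ion pushes the file inward through S_cav."""
    s0, s1, s3, s4 = (st.filter[k] for k in ("S0", "S1", "S3", "S4"))
    records.append(Event(t, "eject", s4, "S4", "CYTO"))
    records.append(Event(t, "shift", s3, "S3", "S4"))
    records.append(Event(t, "shift", s1, "S1", "S3"))
    records.append(Event(t, "shift", s0, "S0", "S1"))
    st.filter.update({"S0": None, "S1": s0, "S3": s1, "S4": s3})
    st.cyto_pool.append(s4)


# --------------------------------------------------------------------------
# Induced knock-on protocol
# --------------------------------------------------------------------------


def apply_induced_knockon(
    params: GeneratorParams,
    t_pull_ns: float = 100.0,
    follow_ns: float = 100.0,
) -> EventLog:
    """Zero-voltage protocol probing whether an S4 vacancy reloads.

    Starting from a 3-ion filter with the inhibitor (if any) bound, the
    central ion is driven outward at ``t_pull_ns``: the outermost ion is
    ejected, the central ion takes its place, the innermost moves to the
    filter center, and S4 is left vacant.  The follow-up window then records
    whether a cytoplasmic ion reloads S4 (rate ``k_reload``, attenuated or
    blocked exactly like ``k_enter``).  At 0 mV a bound TEA may dissociate
    (rate ``tea_unbind``); once unbound at 0 mV it does not re-enter.
    """
    if params.voltage_mV != 0:
        raise ConfigError("the induced knock-on protocol requires 0 mV")
    if t_pull_ns <= 0 or follow_ns <= 0:
        raise ConfigError("t_pull outside the simulated window")
    duration_ns = t_pull_ns + follow_ns
    rng = np.random.default_rng(params.seed)
    atten = params.ry785_attenuation if params.mode == "RY785" else 1.0
    tea_bound = params.mode == "TEA"
    records: list[Event] = []
    initial = {"K0001": "S1", "K0002": "S3", "K0003": "S4"}
    if params.mode == "TEA":
        initial["TEA"] = "BOUND"

    # pre-pull window: the only allowed transition is TEA dissociation
    if tea_bound and params.tea_unbind_per_us > 0:
        t_unbind = rng.exponential(1e3 / params.tea_unbind_per_us)
        if t_unbind < t_pull_ns:
            records.append(Event(t_unbind, "unbind_inhibitor", "TEA", "SCAV", "CYTO"))
            tea_bound = False

    # the pull: S1 ion out, central to S1, innermost to the center
    records.append(Event(t_pull_ns, "eject", "K0001", "S1", "EXT"))
    records.append(Event(t_pull_ns, "induced_pull", "K0002", "S3", "S1"))
    records.append(Event(t_pull_ns, "shift", "K0003", "S4", "S3"))

    # follow-up: TEA may still dissociate; a free pathway reloads S4
    t = t_pull_ns
    while t < duration_ns:
        channels = []
        if tea_bound:
            channels.append((params.tea_unbind_per_us * 1e-3, "tea_unbind"))
        else:
            channels.append((params.k_reload_per_us / atten * 1e-3, "reload"))
        total = sum(r for r, _ in channels)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration_ns:
            break
        u = rng.random() * total
        chosen = channels[0][1] if u <= channels[0][0] else channels[-1][1]
        if chosen == "tea_unbind":
            records.append(Event(t, "unbind_inhibitor", "TEA", "SCAV", "CYTO"))
            tea_bound = False
        else:
            records.append(Event(t, "load", "K0004", "CYTO", "SCAV"))
            records.append(Event(t, "shift", "K0004", "SCAV", "S4"))
            break

    log = EventLog(
        records=records,
        initial=initial,
        duration_ns=duration_ns,
        voltage_mV=0.0,
        mode=params.mode,
    )
    log.validate()
    return log


# --------------------------------------------------------------------------
# Scaffold builder
# --------------------------------------------------------------------------

#: (resname, resid, atom name, radius A, angle offset deg, z A) per subunit.
#: S6 side-chain pseudo-atoms: the V398/I401/P406 side chains face the
#: subunit axis and line the lumen; I405/V409 project toward the A-B-type
#: subunit interfaces, as helix side chains wind around S6.
_S6_LAYOUT = (
    ("VAL", 398, "CG1", 4.0, 0.0, 2.0),
    ("ILE", 401, "CD1", 4.0, 0.0, -1.0),
    ("ILE", 405, "CD1", 5.0, 30.0, -2.75),
    ("PRO", 406, "CG", 4.0, 0.0, -5.5),
    ("VAL", 409, "CG1", 5.0, 30.0, -8.0),
)

_PLANES = (
    ("TYR", 376, "O"),
    ("GLY", 375, "O"),
    ("VAL", 374, "O"),
    ("THR", 373, "O"),
    ("THR", 373, "OG1"),
)


def make_scaffold(
    plane_top_z: float = 14.0,
    spacing: float = 2.8,
    anchor_z: float = 11.0,
    gate_z: float = -10.0,
    filter_radius: float = 1.4,
    anchor_radius: float = 6.0,
    gate_radius: float = 5.0,
) -> Scaffold:
    """Four-fold symmetric pseudo-protein providing every scaffold role.

    Anchors are placed symmetrically about z = 0 so the derived pore model
    uses laboratory z directly; plane offsets are arithmetic with step
    ``spacing`` starting at ``plane_top_z``.  Deterministic.
    """
    names, resnames, resids, chains, roles, pos = [], [], [], [], [], []

    def add(resname, resid, name, role, chain, radius, angle_deg, z):
        theta = math.radians(angle_deg)
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        roles.append(role)
        pos.append((radius * math.cos(theta), radius * math.sin(theta), z))

    for k, chain in enumerate(SUBUNITS):
        base = 90.0 * k
        add("TYR", 376, "CB", ROLE_AXIS_TOP, chain, anchor_radius, base, anchor_z)
        add("VAL", 409, "CB", ROLE_AXIS_BOTTOM, chain, anchor_radius, base, -anchor_z)
        for j, (resname, resid, name) in enumerate(_PLANES):
            add(resname, resid, name, ROLE_FILTER_PLANE, chain,
                filter_radius, base, plane_top_z - j * spacing)
        add("PRO", 408, "CA", ROLE_GATE, chain, gate_radius, base, gate_z)
        for resname, resid, name, radius, dphi, z in _S6_LAYOUT:
            add(resname, resid, name, ROLE_S6, chain, radius, base + dphi, z)

    return Scaffold(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains, dtype=object),
        roles=np.array(roles, dtype=object),
        positions=np.array(pos, dtype=float),
    )


# --------------------------------------------------------------------------
# Coordinate emission
# --------------------------------------------------------------------------

#: TEA's charged nitrogen resides about 1.5 A below the S_cav center
#: (the off-center residence the blocker shows on the intracellular side).
TEA_OFFSET_FROM_SCAV_A = -1.5

#: Rigid 3-site RY785 proxy in axis coordinates relative to the default
#: geometry: (label, element, radius / r0 fraction, angle offset deg,
#: z offset from z_scav A).  The m-methoxybenzene ring carbon is the most
#: extracellular site; the benzimidazole N presses against the wall.
_RY785_SITES = (
    ("RING_C", "C", 0.8, 0.0, 0.9),
    ("THIA_S", "S", 0.8, 0.0, -4.1),
    ("BENZ_N", "N", 1.4, 0.0, -6.1),
)


def emit_coordinates(
    log: EventLog, model: PoreModel, params: GeneratorParams
) -> FrameSet:
    """Realize an event log as frame-sampled noisy 3D coordinates.

    Each ion sits at its compartment's on-axis center plus Gaussian noise
    (``sigma_z``, ``sigma_xy``).  In TEA mode the blocker's N atom sits at
    the on-axis site just below S_cav with lateral spread ``tea_sigma``
    while bound; in RY785 mode the rigid 3-site proxy is parked against the
    S6 wall of one subunit interface with a small rigid-body jitter.
    Seeded by ``params.seed`` (offset so the emission stream is independent
    of the simulation stream).
    """
    n_steps = log.duration_ns / params.frame_interval_ns
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigError("frame interval does not divide the duration")
    rng = np.random.default_rng((int(params.seed), 0xC0FFEE))
    times = np.arange(round(n_steps) + 1) * params.frame_interval_ns
    nf = len(times)

    centers = model.site_centers()
    timelines = log.timelines()
    ions = list(timelines)

    rows = [
        {"atom_id": ion, "kind": "ion", "name": "K", "element": "K",
         "role": "ion", "chain": ""}
        for ion in ions
    ]
    n_ion = len(ions)
    n_extra = 0
    if log.mode == "TEA":
        rows.append({"atom_id": "TEA_N", "kind": "ligand", "name": "N",
                     "element": "N", "role": "ligand_N", "chain": ""})
        n_extra = 1
    elif log.mode == "RY785":
        for label, element, _, _, _ in _RY785_SITES:
            rows.append({"atom_id": f"RY_{label}", "kind": "ligand",
                         "name": label, "element": element,
                         "role": f"ligand_{element}", "chain": ""})
        n_extra = 3
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)

    positions = np.empty((nf, n_ion + n_extra, 3))

    # ions: piecewise-constant compartment -> center + noise
    for j, ion in enumerate(ions):
        t_trans, labels = timelines[ion]
        idx = np.searchsorted(t_trans, times, side="right") - 1
        z = np.array([centers[lab] for lab in labels])[idx]
        if params.sigma_z_A > 0:
            z = z + rng.normal(0.0, params.sigma_z_A, nf)
        xy = (
            rng.normal(0.0, params.sigma_xy_A, (nf, 2))
            if params.sigma_xy_A > 0 else np.zeros((nf, 2))
        )
        positions[:, j, :] = _axis_to_lab(model, z, xy)

    if log.mode == "TEA":
        positions[:, n_ion, :] = _tea_coords(log, model, params, times, rng)
    elif log.mode == "RY785":
        positions[:, n_ion:, :] = _ry785_coords(model, params, nf, rng)

    return FrameSet(times_ns=times, positions=positions, atoms=atoms)


def _axis_to_lab(model: PoreModel, z: np.ndarray, xy: np.ndarray) -> np.ndarray:
    d = model.direction
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (
        model.origin
        + np.outer(z, d)
        + np.outer(xy[:, 0], e1)
        + np.outer(xy[:, 1], e2)
    )


def _tea_coords(log, model, params, times, rng) -> np.ndarray:
    nf = len(times)
    bound = np.zeros(nf, dtype=bool)
    for lo, hi in log.tea_bound_intervals():
        bound |= (times >= lo) & (times <= hi)
    z_site = model.z_scav + TEA_OFFSET_FROM_SCAV_A
    z_free = model.z_floor - 6.0
    z = np.where(bound, z_site, z_free)
    if params.sigma_z_A > 0:
        z = z + rng.normal(0.0, params.sigma_z_A, nf)
    sigma = np.where(bound, params.tea_sigma_A, 2.0)
    xy = rng.normal(0.0, 1.0, (nf, 2)) * sigma[:, None]
    return _axis_to_lab(model, z, xy)


def _ry785_coords(model, params, nf, rng) -> np.ndarray:
    theta0 = math.radians(params.ry785_interface_angle_deg)
    out = np.empty((nf, len(_RY785_SITES), 3))
    jitter = rng.normal(0.0, params.ligand_jitter_A, (nf, 3))  # rigid-body
    for a, (_, _, rfrac, dphi, dz) in enumerate(_RY785_SITES):
        r = rfrac * params.ry785_r0_A
        th = theta0 + math.radians(dphi)
        z = np.full(nf, model.z_scav + dz)
        xy = np.tile([r * math.cos(th), r * math.sin(th)], (nf, 1))
        out[:, a, :] = _axis_to_lab(model, z + jitter[:, 2], xy + jitter[:, :2])
    return out
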