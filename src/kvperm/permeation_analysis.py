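"""From coordinates to permeation statistics.

Turns trajectories (or exact generator event logs) into per-ion compartment
label series and derives the quantities that characterize conduction:
complete permeation events, knock-on cycles, filter occupancy, the
single-channel conductance g = N e / (t V), and the S4 vacancy/reload
diagnostic used to discriminate open-pore block from wall binding.

A complete outward event requires the ion's label to reach EXT with its
axial coordinate at least 1 Å beyond the S0 ceiling (hysteresis against
boundary jitter); the entry time is the last cytoplasmic crossing
preceding completion, or the trajectory start for ions that begin inside
the pore.  Excursions that enter the filter and return count zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

from .errors import InputError
from .frames import FrameSet
from .pore_model import FILTER_SITES, PoreModel
from .synthetic_data import EventLog

_FILTER_SET = frozenset(FILTER_SITES)

# --------------------------------------------------------------------------
# SiteLabelSeries
# --------------------------------------------------------------------------


@dataclass
class IonTrace:
    """Compact per-ion series: label changes at ``times_ns`` (first = t0)."""

    times_ns: np.ndarray
    labels: list[str]
    z: np.ndarray  # axial coordinate at each change, Å


class SiteLabelSeries:
    """Per-ion compartment labels over time, with the axis geometry needed
    for event hysteresis.

    Stored compactly as label-change points; :meth:`dense_labels`
    materializes the one-record-per-ion-per-frame view on the frame grid.
    """

    def __init__(
        self,
        traces: dict[str, IonTrace],
        duration_ns: float,
        frame_interval_ns: float,
        z_out_min: float,
        z_in_max: float,
    ):
        self.traces = traces
        self.duration_ns = float(duration_ns)
        self.frame_interval_ns = float(frame_interval_ns)
        self.z_out_min = float(z_out_min)  # completion threshold, outward
        self.z_in_max = float(z_in_max)  # completion threshold, inward
        for ion, tr in traces.items():
            if np.any(np.diff(tr.times_ns) < 0):
                raise InputError(f"times for ion {ion} are not increasing")

    @property
    def ions(self) -> list[str]:
        return list(self.traces)

    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration_ns / self.frame_interval_ns))
        return np.arange(n + 1) * self.frame_interval_ns

    def dense_labels(self) -> pd.DataFrame:
        """One label per ion per frame (frames as rows, ions as columns)."""
        times = self.frame_times()
        data = {}
        for ion, tr in self.traces.items():
            idx = np.searchsorted(tr.times_ns, times, side="right") - 1
            idx = np.clip(idx, 0, len(tr.labels) - 1)
            data[ion] = np.asarray(tr.labels, dtype=object)[idx]
        return pd.DataFrame(data, index=pd.Index(times, name="time_ns"))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frames(cls, frames: FrameSet, model: PoreModel) -> "SiteLabelSeries":
        """Label every ion in every frame by geometric compartment assignment."""
        idx = frames.indices(kind="ion")
        if len(idx) == 0:
            raise InputError("no atoms with kind 'ion' in the FrameSet")
        traces: dict[str, IonTrace] = {}
        for j in idx:
            ion = str(frames.atoms["atom_id"].iloc[j])
            pos = frames.positions[:, j, :]
            z, r = model.axial_and_radial(pos)
            labels = model._assign_from_zr(z, r)
            # compact to change points (always keep the first frame)
            change = np.empty(len(labels), dtype=bool)
            change[0] = True
            change[1:] = labels[1:] != labels[:-1]
            traces[ion] = IonTrace(
                times_ns=frames.times_ns[change],
                labels=list(labels[change]),
                z=z[change],
            )
        return cls(
            traces=traces,
            duration_ns=float(frames.times_ns[-1]),
            frame_interval_ns=frames.frame_interval_ns or 1.0,
            z_out_min=model.s0_ceiling + 1.0,
            z_in_max=model.z_floor - 1.0,
        )

    @classmethod
    def from_eventlog(
        cls, log: EventLog, model: PoreModel, frame_interval_ns: float = 1.0
    ) -> "SiteLabelSeries":
        """Exact series from a generator log (labels at transition times)."""
        centers = model.site_centers()
        traces = {
            ion: IonTrace(
                times_ns=t,
                labels=labs,
                z=np.array([centers[lab] for lab in labs]),
            )
            for ion, (t, labs) in log.timelines().items()
        }
        return cls(
            traces=traces,
            duration_ns=log.duration_ns,
            frame_interval_ns=frame_interval_ns,
            z_out_min=model.s0_ceiling + 1.0,
            z_in_max=model.z_floor - 1.0,
        )


# --------------------------------------------------------------------------
# Permeation events
# --------------------------------------------------------------------------


@dataclass
class PermeationEvent:
    ion: str
    entry_ns: float
    exit_ns: float
    direction: str  # "outward" | "inward"

    def __post_init__(self) -> None:
        if self.exit_ns < self.entry_ns:
            raise InputError("event exit precedes entry")


def detect_permeation_events(series: SiteLabelSeries) -> list[PermeationEvent]:
    """Complete crossings, separated by direction, disjoint per ion."""
    events: list[PermeationEvent] = []
    for ion, tr in series.traces.items():
        events.extend(_scan_ion(ion, tr, series.z_out_min, series.z_in_max))
    events.sort(key=lambda e: e.exit_ns)
    return events


def _scan_ion(ion, tr, z_out_min, z_in_max):
    events = []
    first = tr.labels[0]
    if first in _FILTER_SET or first in ("SCAV", "CAVITY", "GATE"):
        origin, entry, visited = "PORE", float(tr.times_ns[0]), first in _FILTER_SET
    elif first == "EXT":
        origin, entry, visited = "EXT", None, False
    else:
        origin, entry, visited = "CYTO", None, False
    prev = first
    for t, lab, z in zip(tr.times_ns[1:], tr.labels[1:], tr.z[1:]):
        if lab in _FILTER_SET:
            visited = True
        if prev == "CYTO" and lab != "CYTO" and origin == "CYTO":
            entry = float(t)
            visited = lab in _FILTER_SET
        if prev == "EXT" and lab != "EXT" and origin == "EXT":
            entry = float(t)
            visited = lab in _FILTER_SET
        if lab == "EXT" and z >= z_out_min:
            if origin in ("CYTO", "PORE") and visited:
                events.append(PermeationEvent(ion, entry, float(t), "outward"))
            origin, entry, visited = "EXT", None, False
        elif lab == "CYTO" and z <= z_in_max:
            if origin in ("EXT", "PORE") and visited:
                events.append(PermeationEvent(ion, entry, float(t), "inward"))
            origin, entry, visited = "CYTO", None, False
        prev = lab
    return events


# --------------------------------------------------------------------------
# Scalar statistics
# --------------------------------------------------------------------------


def conductance(n_events: int, duration_us: float, voltage_mV: float) -> float:
    """Single-channel conductance g = n e / (t V), in pS.

    No rounding is applied here; the reporting layer rounds.
    """
    if duration_us <= 0:
        raise ValueError("duration must be positive")
    if voltage_mV == 0:
        raise ValueError("voltage must be nonzero")
    current_A = n_events * constants.e / (duration_us * 1e-6)
    return current_A / (voltage_mV * 1e-3) * 1e12


def mean_interval(n_events: int, duration_us: float) -> float:
    """Mean time between permeation events, μs; NaN signals 'undefined'."""
    if n_events == 0:
        return math.nan
    return duration_us / n_events


# --------------------------------------------------------------------------
# Filter occupancy
# --------------------------------------------------------------------------


@dataclass
class OccupancyStats:
    times_ns: np.ndarray
    counts: np.ndarray
    modal: int
    fractions: dict[int, float]


def filter_occupancy(series: SiteLabelSeries) -> OccupancyStats:
    """Number of ions in sites S0-S4 per frame, plus the modal occupancy.

    S0 counts toward filter occupancy (it is one of the five filter
    sites); S_cav does not.
    """
    deltas: list[tuple[float, int]] = []
    for tr in series.traces.values():
        in_filter = np.array([lab in _FILTER_SET for lab in tr.labels])
        for i, flag in enumerate(in_filter):
            prev_flag = in_filter[i - 1] if i else False
            if flag and not prev_flag:
                deltas.append((float(tr.times_ns[i]), +1))
            elif prev_flag and not flag:
                deltas.append((float(tr.times_ns[i]), -1))
    times = series.frame_times()
    if not deltas:
        counts = np.zeros(len(times), dtype=int)
    else:
        deltas.sort()
        dt = np.array([d[0] for d in deltas])
        dv = np.array([d[1] for d in deltas])
        steps = np.cumsum(dv)
        idx = np.searchsorted(dt, times, side="right") - 1
        counts = np.where(idx >= 0, steps[np.clip(idx, 0, None)], 0)
    occupied = np.bincount(counts)
    modal = int(np.argmax(occupied))
    fractions = {
        k: float(v) / len(counts) for k, v in enumerate(occupied) if v > 0
    }
    return OccupancyStats(times_ns=times, counts=counts, modal=modal,
                          fractions=fractions)


# --------------------------------------------------------------------------
# Knock-on cycles
# --------------------------------------------------------------------------


@dataclass
class KnockOnCycle:
    load_ns: float
    eject_ns: float
    ejected_ion: str
    entering_ion: str

    def __post_init__(self) -> None:
        if self.eject_ns < self.load_ns:
            raise InputError("cycle eject precedes load")


def detect_knockon_cycles(series: SiteLabelSeries) -> list[KnockOnCycle]:
    """Concerted-shift cycles: a 4-ion configuration resolved by ejection.

    Each outward ejection marks a cycle end; the entering ion is the one
    newly occupying S4 alongside it, and the load time is that ion's
    S_cav arrival (falling back to the eject time when the S_cav dwell is
    shorter than the frame interval).
    """
    outward = [e for e in detect_permeation_events(series) if e.direction == "outward"]
    tol = max(series.frame_interval_ns, 1e-6) + 1e-9
    # index S4 arrivals and SCAV arrivals per ion
    s4_arrivals: list[tuple[float, str]] = []
    scav_arrivals: dict[str, np.ndarray] = {}
    for ion, tr in series.traces.items():
        labs = np.asarray(tr.labels, dtype=object)
        s4_idx = np.flatnonzero(labs == "S4")
        for i in s4_idx:
            if i > 0 and tr.labels[i - 1] != "S4":
                s4_arrivals.append((float(tr.times_ns[i]), ion))
        scav_arrivals[ion] = tr.times_ns[
            np.flatnonzero(labs == "SCAV")
        ] if np.any(labs == "SCAV") else np.array([])
    s4_arrivals.sort()
    s4_times = np.array([t for t, _ in s4_arrivals])

    cycles = []
    for ev in outward:
        lo = np.searchsorted(s4_times, ev.exit_ns - tol, side="left")
        hi = np.searchsorted(s4_times, ev.exit_ns + tol, side="right")
        entering, load = "", ev.exit_ns
        for k in range(lo, hi):
            cand = s4_arrivals[k][1]
            if cand != ev.ion:
                entering = cand
                sc = scav_arrivals.get(cand, np.array([]))
                before = sc[sc <= ev.exit_ns + 1e-9]
                if len(before):
                    load = float(before[-1])
                break
        cycles.append(KnockOnCycle(load, ev.exit_ns, ev.ion, entering))
    return cycles


def cycles_per_permeation(series: SiteLabelSeries, ion: str) -> int | None:
    """Knock-on cycles a tagged ion takes from S_cav arrival to its exit."""
    tr = series.traces.get(ion)
    if tr is None:
        raise InputError(f"unknown ion {ion!r}")
    labs = np.asarray(tr.labels, dtype=object)
    arr = np.flatnonzero((labs == "SCAV") | (labs == "S4"))
    if len(arr) == 0:
        return None
    t_arr = float(tr.times_ns[arr[0]])
    exits = [
        e for e in detect_permeation_events(series)
        if e.ion == ion and e.direction == "outward" and e.exit_ns >= t_arr
    ]
    if not exits:
        return None
    t_exit = exits[0].exit_ns
    cycles = detect_knockon_cycles(series)
    return sum(1 for c in cycles if t_arr < c.eject_ns <= t_exit + 1e-9)


# --------------------------------------------------------------------------
# S4 vacancy / reload diagnostic
# --------------------------------------------------------------------------


@dataclass
class ReloadResult:
    latency_ns: float | None
    vacancy: bool  # False flags the degenerate "S4 never vacated" case


def s4_reload(series: SiteLabelSeries, t_pull_ns: float,
              window_ns: float = 100.0) -> ReloadResult:
    """Latency until an ion reoccupies S4 after the induced vacancy.

    Returns latency 0 with ``vacancy=False`` when S4 never vacates (no
    pull applied); ``latency=None`` when no reload occurs inside the
    window.
    """
    if not (0.0 <= t_pull_ns <= series.duration_ns):
        raise InputError("t_pull outside the series")
    intervals = []  # (start, end) of S4 occupancy by any ion
    for ion, tr in series.traces.items():
        labs = tr.labels
        for i, lab in enumerate(labs):
            if lab == "S4":
                start = float(tr.times_ns[i])
                end = float(tr.times_ns[i + 1]) if i + 1 < len(labs) else series.duration_ns
                intervals.append((start, end))
    intervals.sort()
    eps = 1e-9
    for start, end in intervals:
        if start <= t_pull_ns + eps < end:
            return ReloadResult(latency_ns=0.0, vacancy=False)
    starts = [s for s, _ in intervals if s > t_pull_ns + eps]
    if starts and starts[0] - t_pull_ns <= window_ns:
        return ReloadResult(latency_ns=float(starts[0] - t_pull_ns), vacancy=True)
    return ReloadResult(latency_ns=None, vacancy=True)


# --------------------------------------------------------------------------
# Rate ratio with bootstrap CI
# --------------------------------------------------------------------------


@dataclass
class RateRatioResult:
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def rate_ratio(
    events_a,
    duration_a_us: float,
    events_b,
    duration_b_us: float,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> RateRatioResult:
    """(rate A)/(rate B) with a seeded percentile bootstrap CI over events.

    ``events_*`` may be an event count or a sequence of event times (same
    unit as the durations); with times, interarrival intervals are
    resampled (renewal bootstrap), with counts a Poisson bootstrap is used.
    A zero count in the denominator yields NaN (undefined-ratio signal).
    """
    n_a, boot_a = _rate_samples(events_a, duration_a_us, n_boot, seed)
    n_b, boot_b = _rate_samples(events_b, duration_b_us, n_boot, seed + 1)
    if n_b == 0 or n_a == 0:
        return RateRatioResult(math.nan, math.nan, math.nan, n_boot)
    ratio = (n_a / duration_a_us) / (n_b / duration_b_us)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = boot_a / boot_b
    ratios = ratios[np.isfinite(ratios)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return RateRatioResult(float(ratio), float(lo), float(hi), n_boot)


def _rate_samples(events, duration, n_boot, seed):
    rng = np.random.default_rng(seed)
    if np.isscalar(events):
        n = int(events)
        return n, rng.poisson(max(n, 0), n_boot) / duration
    times = np.sort(np.asarray(events, dtype=float))
    n = len(times)
    if n == 0:
        return 0, np.zeros(n_boot)
    intervals = np.diff(np.concatenate([[0.0], times]))
    picks = rng.integers(0, n, (n_boot, n))
    tot = intervals[picks].sum(axis=1)
    return n, np.where(tot > 0, n / tot, np.nan)
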