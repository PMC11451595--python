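"""Event detection, conductance, occupancy, cycles, reload, rate ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kvperm import (
    GeneratorParams,
    SiteLabelSeries,
    apply_induced_knockon,
    conductance,
    cycles_per_permeation,
    detect_knockon_cycles,
    detect_permeation_events,
    filter_occupancy,
    mean_interval,
    rate_ratio,
    s4_reload,
    simulate_knockon,
)
from kvperm.errors import InputError
from kvperm.permeation_analysis import IonTrace


def _series_from_traces(model, traces, duration_ns):
    return SiteLabelSeries(
        traces=traces,
        duration_ns=duration_ns,
        frame_interval_ns=1.0,
        z_out_min=model.s0_ceiling + 1.0,
        z_in_max=model.z_floor - 1.0,
    )


def _trace(model, times, labels):
    centers = model.site_centers()
    return IonTrace(
        times_ns=np.asarray(times, dtype=float),
        labels=list(labels),
        z=np.array([centers[lab] for lab in labels]),
    )


# -- detector on hand-built traces ------------------------------------------


def test_full_outward_crossing_counts_once(model):
    tr = _trace(model, [0, 10, 20, 30, 40, 50],
                ["CYTO", "SCAV", "S4", "S3", "S1", "EXT"])
    series = _series_from_traces(model, {"K": tr}, 60.0)
    events = detect_permeation_events(series)
    assert len(events) == 1
    ev = events[0]
    assert ev.direction == "outward"
    assert ev.entry_ns == pytest.approx(10.0)
    assert ev.exit_ns == pytest.approx(50.0)


def test_entry_is_last_cytoplasmic_departure(model):
    tr = _trace(model, [0, 10, 20, 30, 40, 50],
                ["CYTO", "SCAV", "CYTO", "SCAV", "S4", "EXT"])
    # one failed excursion, then a complete crossing
    series = _series_from_traces(model, {"K": tr}, 60.0)
    events = detect_permeation_events(series)
    assert len(events) == 1
    assert events[0].entry_ns == pytest.approx(30.0)


def test_failed_excursion_counts_zero(model):
    tr = _trace(model, [0, 10, 20, 30],
                ["CYTO", "SCAV", "S4", "CYTO"])
    series = _series_from_traces(model, {"K": tr}, 40.0)
    # did not exit beyond the floor hysteresis from inside: returning to
    # CYTO from its own side is not a crossing
    assert detect_permeation_events(series) == []


def test_top_excursion_counts_zero(model):
    tr = _trace(model, [0, 10, 20], ["EXT", "S0", "EXT"])
    series = _series_from_traces(model, {"E": tr}, 30.0)
    assert detect_permeation_events(series) == []


def test_inward_crossing_detected(model):
    tr = _trace(model, [0, 10, 20, 30, 40, 50],
                ["EXT", "S0", "S1", "S3", "S4", "CYTO"])
    series = _series_from_traces(model, {"E": tr}, 60.0)
    events = detect_permeation_events(series)
    assert len(events) == 1
    assert events[0].direction == "inward"
    assert events[0].entry_ns == pytest.approx(10.0)


def test_pore_starting_ion_entry_at_t0(model):
    tr = _trace(model, [0, 10, 20], ["S3", "S1", "EXT"])
    series = _series_from_traces(model, {"K": tr}, 30.0)
    events = detect_permeation_events(series)
    assert len(events) == 1
    assert events[0].entry_ns == pytest.approx(0.0)


def test_hysteresis_blocks_boundary_jitter(model):
    centers = model.site_centers()
    tr = IonTrace(
        times_ns=np.array([0.0, 10.0, 20.0, 30.0]),
        labels=["S1", "S0", "EXT", "S0"],
        # the EXT excursion stays below the +1 A completion threshold
        z=np.array([centers["S1"], centers["S0"],
                    model.s0_ceiling + 0.5, centers["S0"]]),
    )
    series = _series_from_traces(model, {"K": tr}, 40.0)
    assert detect_permeation_events(series) == []


def test_detector_equals_log_eject_count(base_log, base_series):
    outward = [e for e in detect_permeation_events(base_series)
               if e.direction == "outward"]
    assert len(outward) == base_log.eject_count


def test_detector_equals_log_across_seeds(model):
    for seed in range(5):
        log = simulate_knockon(GeneratorParams(seed=seed, duration_us=3.0))
        series = SiteLabelSeries.from_eventlog(log, model)
        outward = [e for e in detect_permeation_events(series)
                   if e.direction == "outward"]
        inward = [e for e in detect_permeation_events(series)
                  if e.direction == "inward"]
        assert len(outward) == log.eject_count
        assert len(inward) == log.inward_count


def test_event_times_are_ordered(base_series):
    events = detect_permeation_events(base_series)
    exits = [e.exit_ns for e in events]
    assert exits == sorted(exits)
    for e in events:
        assert e.entry_ns <= e.exit_ns


# -- scalar statistics -------------------------------------------------------


def test_conductance_worked_example():
    assert conductance(45, 24.5, 100.0) == pytest.approx(2.9428, abs=1e-3)


def test_conductance_errors():
    with pytest.raises(ValueError):
        conductance(1, 0.0, 100.0)
    with pytest.raises(ValueError):
        conductance(1, 1.0, 0.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(1, 1000), st.floats(0.1, 100.0), st.floats(1.0, 500.0),
       st.integers(2, 5))
def test_conductance_homogeneity(n, t, v, scale):
    assert conductance(scale * n, scale * t, v) == pytest.approx(
        conductance(n, t, v), rel=1e-9
    )


def test_mean_interval():
    assert mean_interval(45, 24.5) == pytest.approx(24.5 / 45)
    assert math.isnan(mean_interval(0, 24.5))


# -- occupancy ---------------------------------------------------------------


def test_filter_occupancy_modal_three(base_series):
    occ = filter_occupancy(base_series)
    assert occ.modal == 3
    assert occ.fractions[3] > 0.5
    assert set(np.unique(occ.counts)) <= {0, 1, 2, 3, 4, 5}
    assert abs(sum(occ.fractions.values()) - 1.0) < 1e-9


def test_filter_occupancy_counts_s0_not_scav(model):
    traces = {
        "A": _trace(model, [0.0], ["S0"]),
        "B": _trace(model, [0.0], ["SCAV"]),
        "C": _trace(model, [0.0], ["S3"]),
    }
    series = _series_from_traces(model, traces, 10.0)
    occ = filter_occupancy(series)
    assert occ.modal == 2  # S0 and S3 count, S_cav does not


# -- knock-on cycles ---------------------------------------------------------


@pytest.fixture(scope="module")
def forced_series(model):
    params = GeneratorParams(seed=21, duration_us=3.0, force_eject=True)
    log = simulate_knockon(params)
    return SiteLabelSeries.from_eventlog(log, model), log


def test_cycles_match_ejections(forced_series):
    series, log = forced_series
    cycles = detect_knockon_cycles(series)
    assert len(cycles) == log.eject_count
    for c in cycles:
        assert c.load_ns <= c.eject_ns
        assert c.entering_ion != c.ejected_ion


def test_tagged_ion_crosses_in_four_cycles(forced_series):
    series, log = forced_series
    # the first freshly loaded cytoplasmic ion
    tagged = next(r.ion for r in log.records if r.event == "load")
    assert cycles_per_permeation(series, tagged) == 4


def test_cycles_per_permeation_unknown_ion(base_series):
    with pytest.raises(InputError):
        cycles_per_permeation(base_series, "K9999")


# -- S4 reload diagnostic ----------------------------------------------------


def test_s4_reload_latency(model):
    p = GeneratorParams(seed=0, voltage_mV=0.0)
    log = apply_induced_knockon(p, t_pull_ns=100.0, follow_ns=100.0)
    series = SiteLabelSeries.from_eventlog(log, model)
    result = s4_reload(series, 100.0)
    assert result.vacancy
    assert result.latency_ns is not None
    assert 0.0 < result.latency_ns <= 100.0


def test_s4_reload_degenerate_no_pull(base_series):
    # S4 is occupied in the steady automaton at any typical instant
    result = s4_reload(base_series, 0.0)
    assert not result.vacancy
    assert result.latency_ns == 0.0


def test_s4_reload_bad_time(base_series):
    with pytest.raises(InputError):
        s4_reload(base_series, -5.0)
    with pytest.raises(InputError):
        s4_reload(base_series, base_series.duration_ns + 1.0)


# -- rate ratio --------------------------------------------------------------


def test_rate_ratio_point_estimate():
    res = rate_ratio(40, 10.0, 10, 10.0, seed=0)
    assert res.ratio == pytest.approx(4.0)
    assert res.ci_low < 4.0 < res.ci_high


def test_rate_ratio_zero_denominator_is_nan():
    res = rate_ratio(40, 10.0, 0, 10.0, seed=0)
    assert math.isnan(res.ratio)


def test_rate_ratio_accepts_event_times():
    rng = np.random.default_rng(5)
    times_a = np.sort(rng.uniform(0.0, 10.0, 40))
    times_b = np.sort(rng.uniform(0.0, 10.0, 10))
    res = rate_ratio(times_a, 10.0, times_b, 10.0, seed=0)
    assert res.ratio == pytest.approx(4.0)
    assert res.ci_low < res.ratio < res.ci_high


def test_rate_ratio_deterministic():
    a = rate_ratio(30, 5.0, 12, 5.0, seed=42)
    b = rate_ratio(30, 5.0, 12, 5.0, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_rate_ratio_ci_narrows_with_counts():
    narrow = rate_ratio(4000, 1000.0, 1000, 1000.0, seed=0)
    wide = rate_ratio(40, 10.0, 10, 10.0, seed=0)
    assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)
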