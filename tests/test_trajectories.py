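"""Trajectory IO, normalization, featurization and comparison tests."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foxmdyn import synthetic as syn
from foxmdyn import trajectories as traj

GRID = syn.default_time_grid()


def make_trace(y, cell_id="c0", drug="DMSO", dose=0.0, cyto=(), times=None):
    times = GRID if times is None else times
    return traj.Trace(
        cell_id=cell_id, drug=drug, dose=dose, batch="B1",
        times=times, intensities=np.asarray(y, dtype=float),
        cytokinesis_times=list(cyto),
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _three_cell_set():
    rng = np.random.default_rng(0)
    traces = [
        make_trace(rng.uniform(0.5, 2.0, GRID.size), cell_id=f"c{i}",
                   drug="BI2536", dose=10.0, cyto=[24.0 + i])
        for i in range(3)
    ]
    return traj.TraceSet(traces)

def test_write_read_round_trip(tmp_path):
    original = _three_cell_set()
    path = tmp_path / "t.csv"
    traj.write_traces(original, path)
    back = traj.read_traces(path)
    assert len(back) == 3
    for a, b in zip(original, back):
        assert a.cell_id == b.cell_id
        assert a.drug == b.drug and a.dose == b.dose and a.batch == b.batch
        np.testing.assert_allclose(a.times, b.times)
        np.testing.assert_allclose(a.intensities, b.intensities)
        assert a.cytokinesis_times == pytest.approx(b.cytokinesis_times)
        assert a.truth_label == b.truth_label


def test_duplicate_cell_time_rejected(tmp_path):
    path = tmp_path / "t.csv"
    original = _three_cell_set()
    df = original.to_frame()
    df = df._append(df.iloc[0])
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="duplicated"):
        traj.read_traces(path)


def test_header_only_file_gives_empty_set(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(",".join(traj.TRACE_COLUMNS) + "\n")
    assert len(traj.read_traces(path)) == 0


def test_missing_column_rejected(tmp_path):
    path = tmp_path / "t.csv"
    df = _three_cell_set().to_frame().drop(columns=["intensity"])
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing columns"):
        traj.read_traces(path)


def test_nan_intensity_rejected(tmp_path):
    path = tmp_path / "t.csv"
    df = _three_cell_set().to_frame()
    df.loc[5, "intensity"] = np.nan
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="NaN intensity"):
        traj.read_traces(path)


def test_irregular_grid_rejected(tmp_path):
    path = tmp_path / "t.csv"
    df = _three_cell_set().to_frame()
    df = df.drop(index=[4])  # puncture one cell's grid
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="uniform"):
        traj.read_traces(path)


def test_cytokinesis_time_outside_grid_rejected():
    with pytest.raises(ValueError, match="outside grid"):
        make_trace(np.ones(GRID.size), cyto=[49.0])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_constant_traces_normalize_to_one():
    ts = traj.TraceSet([make_trace(np.full(GRID.size, 5.0))])
    out = traj.normalize_to_initial_mean(ts, window_frames=6)
    np.testing.assert_allclose(out[0].intensities, 1.0)


def test_two_conditions_each_unit_initial_mean():
    ts = traj.TraceSet(
        [
            make_trace(np.full(GRID.size, 2.0), cell_id="a", drug="A"),
            make_trace(np.full(GRID.size, 8.0), cell_id="b", drug="B"),
        ]
    )
    out = traj.normalize_to_initial_mean(ts, window_frames=6)
    for tr in out:
        assert abs(tr.intensities[:6].mean() - 1.0) < 1e-9


def test_normalization_idempotent(small_panel):
    once = traj.normalize_to_initial_mean(small_panel)
    twice = traj.normalize_to_initial_mean(once)
    np.testing.assert_allclose(twice.matrix(), once.matrix(), atol=1e-12)


def test_zero_initial_mean_rejected():
    y = np.ones(GRID.size)
    y[:6] = 0.0
    ts = traj.TraceSet([make_trace(y)])
    with pytest.raises(ValueError, match="DMSO@0"):
        traj.normalize_to_initial_mean(ts, window_frames=6)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def test_smooth_window_one_is_identity():
    tr = make_trace(np.random.default_rng(1).uniform(0, 2, GRID.size))
    np.testing.assert_array_equal(traj.smooth(tr, 1).intensities, tr.intensities)


def test_smooth_constant_unchanged():
    tr = make_trace(np.full(GRID.size, 1.5))
    np.testing.assert_allclose(traj.smooth(tr, 7).intensities, 1.5)


def test_smooth_linear_ramp_unchanged_in_interior():
    tr = make_trace(np.linspace(0.0, 2.0, GRID.size))
    sm = traj.smooth(tr, 5)
    np.testing.assert_allclose(sm.intensities[2:-2], tr.intensities[2:-2], atol=1e-12)


def test_smooth_even_window_rejected():
    tr = make_trace(np.ones(GRID.size))
    with pytest.raises(ValueError, match="odd"):
        traj.smooth(tr, 4)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


def test_monotone_trace_has_no_interior_peaks():
    tr = make_trace(np.linspace(0.5, 2.5, GRID.size))
    f = traj.detect_peaks(tr)
    assert f.n_peaks == 0
    assert f.t_peak1 is None
    assert f.terminal_slope > 0


def test_two_bump_archetype_peaks_at_4_and_24():
    p = replace(
        syn.default_archetypes()["on_time_cytokinesis"], cv_cell=0.0, sigma_noise=0.0
    )
    tr = syn.simulate_trace(p, GRID, seed=0)
    f = traj.detect_peaks(tr)
    assert f.n_peaks == 2
    assert abs(f.t_peak1 - 4.0) <= 1 / 6 + 1e-9
    assert abs(f.t_peak2 - 24.0) <= 1 / 6 + 1e-9
    assert f.onset_t1 is not None and f.onset_t1 <= f.t_peak1


def _brute_force_peaks(y, min_prom_frac, min_sep_frames):
    """Independent oracle: interior strict local maxima filtered greedily."""
    y = np.asarray(y, dtype=float)
    cand = [
        i
        for i in range(1, y.size - 1)
        if y[i] > y[i - 1] and y[i] >= y[i + 1]
    ]
    # prominence by direct contour walk
    rng = y.max() - y.min()
    out = []
    for i in cand:
        left = y[:i][::-1]
        right = y[i + 1 :]
        higher_l = np.nonzero(left > y[i])[0]
        higher_r = np.nonzero(right > y[i])[0]
        lmin = left[: higher_l[0]].min() if higher_l.size else left.min()
        rmin = right[: higher_r[0]].min() if higher_r.size else right.min()
        prom = y[i] - max(lmin, rmin)
        if prom >= min_prom_frac * rng:
            out.append(i)
    # enforce separation, keeping higher peaks first (matches scipy)
    keep = []
    for i in sorted(out, key=lambda j: -y[j]):
        if all(abs(i - j) >= min_sep_frames for j in keep):
            keep.append(i)
    return sorted(keep)


@pytest.mark.parametrize("name", syn.ARCHETYPES)
def test_peak_detector_agrees_with_brute_force_oracle(name):
    p = replace(syn.default_archetypes()[name], cv_cell=0.0, sigma_noise=0.0)
    tr = syn.simulate_trace(p, GRID, seed=0)
    f = traj.detect_peaks(tr, min_prominence=0.1, min_separation=3.0)
    expected = _brute_force_peaks(tr.intensities, 0.1, int(round(3.0 * 6)))
    assert f.n_peaks == len(expected)
    if expected:
        assert f.t_peak1 == pytest.approx(GRID[expected[0]])
    if len(expected) >= 2:
        assert f.t_peak2 == pytest.approx(GRID[expected[1]])


def test_amplitudes_are_pulse_prominences():
    p = replace(
        syn.default_archetypes()["cytokinesis_delay"], cv_cell=0.0, sigma_noise=0.0
    )
    tr = syn.simulate_trace(p, GRID, seed=0)
    f = traj.detect_peaks(tr)
    # second pulse: height a_peak2 above the inter-pulse trough near baseline
    assert f.a_peak2 == pytest.approx(p.a_peak2, rel=0.01)
    assert f.a_peak1 < p.a_peak1  # first pulse measured above its own base


def test_short_trace_rejected():
    with pytest.raises(ValueError, match="too short"):
        traj.detect_peaks(make_trace([1.0, 2.0], times=np.array([0.0, 1 / 6])))


def test_bad_prominence_rejected():
    tr = make_trace(np.ones(GRID.size))
    with pytest.raises(ValueError, match="min_prominence"):
        traj.detect_peaks(tr, min_prominence=1.5)


# ---------------------------------------------------------------------------
# population means
# ---------------------------------------------------------------------------


def test_population_mean_single_cell():
    tr = make_trace(np.linspace(1, 2, GRID.size))
    pop = traj.population_mean_trajectory(traj.TraceSet([tr]))["DMSO@0"]
    np.testing.assert_allclose(pop.mean, tr.intensities)
    np.testing.assert_allclose(pop.sd, 0.0)
    assert pop.n == 1


def test_population_mean_two_constants():
    ts = traj.TraceSet(
        [
            make_trace(np.full(GRID.size, 1.0), cell_id="a"),
            make_trace(np.full(GRID.size, 3.0), cell_id="b"),
        ]
    )
    pop = traj.population_mean_trajectory(ts)["DMSO@0"]
    np.testing.assert_allclose(pop.mean, 2.0)
    np.testing.assert_allclose(pop.sd, math.sqrt(2.0))


def test_population_mean_mirrored_fluctuations_cancel():
    rng = np.random.default_rng(3)
    f = np.clip(rng.normal(0, 0.2, GRID.size), -0.9, 0.9)
    ts = traj.TraceSet(
        [
            make_trace(1.0 + f, cell_id="a"),
            make_trace(1.0 - f, cell_id="b"),
        ]
    )
    pop = traj.population_mean_trajectory(ts)["DMSO@0"]
    np.testing.assert_allclose(pop.mean, 1.0, atol=1e-12)


def test_population_mean_empty_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        traj.population_mean_trajectory(traj.TraceSet([]))


# ---------------------------------------------------------------------------
# half-life
# ---------------------------------------------------------------------------


def test_half_life_exact_exponential():
    y = np.exp(-math.log(2.0) * GRID)
    assert traj.estimate_half_life(make_trace(y)) == pytest.approx(1.0, rel=1e-9)


def test_half_life_faster_exponential():
    y = np.exp(-2 * math.log(2.0) * GRID)
    assert traj.estimate_half_life(make_trace(y)) == pytest.approx(0.5, rel=1e-9)


def test_half_life_noiseless_cycloheximide_within_1pct():
    trace = syn.simulate_perturbation_trace("cycloheximide")
    assert traj.estimate_half_life(trace) == pytest.approx(0.5, rel=0.01)


def test_half_life_noisy_unbiased_within_10pct():
    # mean estimate over replicates at 5% noise stays within 10% of truth
    estimates = []
    for seed in range(50):
        trace = syn.simulate_perturbation_trace(
            "cycloheximide", params={"sigma_noise": 0.05}, seed=seed
        )
        y = np.clip(trace.intensities, 1e-6, None)
        # fit over the first decade of decay, where the signal dominates the
        # additive noise and the log transform stays well-conditioned
        estimates.append(traj.estimate_half_life(make_trace(y, times=trace.times),
                                                 fit_window=(0.0, 1.0)))
    assert np.mean(estimates) == pytest.approx(0.5, rel=0.10)


def test_half_life_no_decay_rejected():
    y = np.exp(0.1 * GRID)
    with pytest.raises(ValueError, match="no decay detected"):
        traj.estimate_half_life(make_trace(y))


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


def _feature_group(n, a2=2.0, t2=24.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        traj.PeakFeatureRecord(
            cell_id=f"c{i}", condition="X@1", n_peaks=2, t_peak1=4.0, a_peak1=1.5,
            t_peak2=t2 + rng.normal(0, 0.2), a_peak2=a2 + rng.normal(0, 0.05),
            onset_t1=2.0, terminal_slope=-0.01,
        )
        for i in range(n)
    ]


def test_compare_identical_groups():
    a = _feature_group(30)
    rep = traj.compare_conditions(a, a, [[26.0]] * 30, [[26.0]] * 30)
    assert rep.amplitude_fold_change == pytest.approx(1.0)
    assert rep.peak2_time_diff_h == pytest.approx(0.0)
    assert rep.cytokinesis_diff_h == pytest.approx(0.0)


def test_compare_halved_amplitudes_fold_half():
    a = _feature_group(30)
    b = [replace(f, a_peak2=f.a_peak2 / 2.0) for f in a]
    rep = traj.compare_conditions(a, b)
    assert rep.amplitude_fold_change == pytest.approx(0.5, rel=1e-9)


def test_compare_antisymmetric_and_reciprocal():
    a = _feature_group(30, seed=1)
    b = _feature_group(30, a2=1.0, t2=20.0, seed=2)
    ab = traj.compare_conditions(a, b, [[26.0]] * 30, [[24.0]] * 30)
    ba = traj.compare_conditions(b, a, [[24.0]] * 30, [[26.0]] * 30)
    assert ab.peak2_time_diff_h == pytest.approx(-ba.peak2_time_diff_h)
    assert ab.cytokinesis_diff_h == pytest.approx(-ba.cytokinesis_diff_h)
    assert ab.amplitude_fold_change == pytest.approx(1.0 / ba.amplitude_fold_change)


def test_compare_absent_metric_reported_none():
    a = _feature_group(10)
    b = [replace(f, t_peak2=None, a_peak2=None) for f in _feature_group(10)]
    rep = traj.compare_conditions(a, b)
    assert rep.amplitude_fold_change is None
    assert rep.peak2_time_diff_h is None
    assert rep.cytokinesis_diff_h is None


def test_compare_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        traj.compare_conditions([], _feature_group(5))


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_normalization_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    grid = np.arange(30) / 6.0
    ts = traj.TraceSet(
        [
            make_trace(rng.uniform(0.2, 3.0, grid.size), cell_id=f"c{i}", times=grid)
            for i in range(4)
        ]
    )
    once = traj.normalize_to_initial_mean(ts, window_frames=6)
    twice = traj.normalize_to_initial_mean(once, window_frames=6)
    np.testing.assert_allclose(twice.matrix(), once.matrix(), atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=0.05, max_value=4.0))
def test_half_life_property_recovers_rate(scale, half_life):
    grid = np.arange(60) / 6.0
    y = scale * np.exp(-math.log(2.0) / half_life * grid)
    est = traj.estimate_half_life(make_trace(y, times=grid))
    assert est == pytest.approx(half_life, rel=1e-6)
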