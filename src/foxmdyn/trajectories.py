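"""Single-cell reporter trajectory containers, IO, and featurization.

A :class:`Trace` is one cell's nuclear reporter intensity sampled on a
uniform time grid (10-min frames over 48 h by default), together with its
treatment metadata and any recorded cytokinesis event times.  The functions
here cover the bulk-dynamics workflow: normalization to the initial
per-condition mean, moving-average smoothing, peak featurization (first/second
peak time and amplitude, onset time, terminal slope), population-mean
trajectories (mean +/- sample SD), log-linear protein half-life estimation,
and two-group comparisons of pulse features with Welch t-tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "Trace",
    "TraceSet",
    "PeakFeatureRecord",
    "ComparisonReport",
    "read_traces",
    "write_traces",
    "normalize_to_initial_mean",
    "smooth",
    "detect_peaks",
    "population_mean_trajectory",
    "estimate_half_life",
    "compare_conditions",
]

#: Column order of the long-format trace table.
TRACE_COLUMNS = [
    "cell_id",
    "drug",
    "dose_uM",
    "batch",
    "archetype_truth",
    "time_h",
    "intensity",
    "cytokinesis_time_h",
]

_GRID_RTOL = 1e-6


def _check_uniform_grid(times: np.ndarray) -> float:
    """Return the grid step, raising if the grid is not uniform increasing."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("time grid must be a 1-D vector with >= 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * max(dt, 1.0)):
        raise ValueError("time grid must be uniform (irregular grids are rejected)")
    return float(dt)


@dataclass
class Trace:
    """One cell's reporter intensity time series with metadata."""

    cell_id: str
    drug: str
    dose: float
    batch: str
    times: np.ndarray
    intensities: np.ndarray
    cytokinesis_times: list[float] = field(default_factory=list)
    truth_label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _check_uniform_grid(self.times)
        if self.intensities.shape != self.times.shape:
            raise ValueError("times and intensities must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"trace {self.cell_id!r}: non-finite intensity")
        if np.any(self.intensities < 0):
            raise ValueError(f"trace {self.cell_id!r}: negative intensity")
        lo, hi = self.times[0], self.times[-1]
        for t in self.cytokinesis_times:
            if not (lo <= t <= hi):
                raise ValueError(
                    f"trace {self.cell_id!r}: cytokinesis time {t} outside grid"
                )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def condition(self) -> str:
        """Condition key used for grouping: drug at a dose."""
        return f"{self.drug}@{self.dose:g}"

    def copy(self, **updates) -> "Trace":
        kwargs = dict(
            cell_id=self.cell_id,
            drug=self.drug,
            dose=self.dose,
            batch=self.batch,
            times=self.times.copy(),
            intensities=self.intensities.copy(),
            cytokinesis_times=list(self.cytokinesis_times),
            truth_label=self.truth_label,
        )
        kwargs.update(updates)
        return Trace(**kwargs)


class TraceSet:
    """An ordered collection of traces sharing one time grid."""

    def __init__(self, traces: Sequence[Trace]):
        self.traces: list[Trace] = list(traces)
        if self.traces:
            grid = self.traces[0].times
            for tr in self.traces[1:]:
                if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
                    raise ValueError("all traces in a TraceSet must share one grid")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> Trace:
        return self.traces[i]

    @property
    def grid(self) -> np.ndarray:
        if not self.traces:
            raise ValueError("empty TraceSet has no grid")
        return self.traces[0].times

    def matrix(self) -> np.ndarray:
        """Stack intensities into a (n_traces, n_timepoints) array."""
        return np.vstack([tr.intensities for tr in self.traces])

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.traces:
            seen.setdefault(tr.condition, None)
        return list(seen)

    def groupby(self, key: str = "condition") -> dict[str, "TraceSet"]:
        groups: dict[str, list[Trace]] = {}
        for tr in self.traces:
            k = getattr(tr, key)
            groups.setdefault(k, []).append(tr)
        return {k: TraceSet(v) for k, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            cyto = ";".join(f"{t:.6g}" for t in tr.cytokinesis_times)
            for t, y in zip(tr.times, tr.intensities):
                rows.append(
                    (tr.cell_id, tr.drug, tr.dose, tr.batch,
                     tr.truth_label or "", t, y, cyto)
                )
        return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_traces(trace_set: TraceSet, path) -> None:
    """Write a TraceSet as a long-format CSV."""
    trace_set.to_frame().to_csv(path, index=False)


def _parse_cyto(raw) -> list[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return []
    s = str(raw).strip()
    if not s:
        return []
    return [float(tok) for tok in s.split(";")]


def read_traces(path) -> TraceSet:
    """Read a long-format trace CSV into a TraceSet.

    Rows are grouped per cell and sorted by time; malformed input (missing
    columns, duplicate time points, NaN intensities, irregular grids) raises
    with enough context to locate the offending rows.
    """
    df = pd.read_csv(path, comment="#", dtype={"cell_id": str, "batch": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table {path}: missing columns {missing}")
    if df.empty:
        return TraceSet([])
    dup = df.duplicated(subset=["cell_id", "time_h"])
    if dup.any():
        row = df.index[dup][0]
        key = df.loc[row, ["cell_id", "time_h"]].tolist()
        raise ValueError(f"trace table {path}: duplicated (cell_id, time_h) {key} at row {row}")
    if df["intensity"].isna().any():
        row = int(df.index[df["intensity"].isna()][0])
        raise ValueError(f"trace table {path}: NaN intensity at row {row}")
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_h")
        truth = str(g["archetype_truth"].iloc[0]) if not pd.isna(g["archetype_truth"].iloc[0]) else ""
        traces.append(
            Trace(
                cell_id=str(cell_id),
                drug=str(g["drug"].iloc[0]),
                dose=float(g["dose_uM"].iloc[0]),
                batch=str(g["batch"].iloc[0]),
                times=g["time_h"].to_numpy(dtype=float),
                intensities=g["intensity"].to_numpy(dtype=float),
                cytokinesis_times=_parse_cyto(g["cytokinesis_time_h"].iloc[0]),
                truth_label=truth or None,
            )
        )
    return TraceSet(traces)


def normalize_to_initial_mean(trace_set: TraceSet, window_frames: int = 6) -> TraceSet:
    """Divide every trace by its condition's mean intensity over the first frames.

    Mirrors the convention of reporting intensities relative to the initial
    mean fluorescence of each condition, so the per-condition mean of the
    first window equals 1 after normalization.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if trace_set.traces and window_frames > trace_set.grid.size:
        raise ValueError("window_frames exceeds grid length")
    out = []
    for cond, group in trace_set.groupby("condition").items():
        m = float(np.mean(group.matrix()[:, :window_frames]))
        if m <= 0:
            raise ValueError(f"condition {cond!r}: non-positive initial mean {m}")
        for tr in group:
            out.append(tr.copy(intensities=tr.intensities / m))
    return TraceSet(out)


def smooth(trace: Trace, window_frames: int = 5) -> Trace:
    """Centered moving average; edge windows shrink. window_frames must be odd."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    if window_frames == 1:
        return trace.copy()
    sm = (
        pd.Series(trace.intensities)
        .rolling(window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return trace.copy(intensities=sm)


@dataclass
class PeakFeatureRecord:
    """Pulse features of one trajectory."""

    cell_id: str
    condition: str
    n_peaks: int
    t_peak1: float | None
    a_peak1: float | None
    t_peak2: float | None
    a_peak2: float | None
    onset_t1: float | None
    terminal_slope: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def detect_peaks(
    trace: Trace,
    min_prominence: float = 0.1,
    min_separation: float = 3.0,
    rise_fraction: float = 0.5,
    terminal_window: float = 6.0,
) -> PeakFeatureRecord:
    """Find interior local maxima and derive pulse features.

    ``min_prominence`` is a fraction of the trace's intensity range;
    ``min_separation`` is in hours.  Pulse amplitudes ``a_peak1``/``a_peak2``
    are peak prominences (pulse height above its base), so they measure the
    pulse itself rather than the absolute level.  ``onset_t1`` is the
    earliest time the trace climbs ``rise_fraction`` of the first pulse's
    prominence above the pulse base, at or before the peak;
    ``terminal_slope`` is the least-squares slope over the final
    ``terminal_window`` hours.
    """
    y = trace.intensities
    if y.size < 3:
        raise ValueError("trace too short for peak detection")
    if not np.any(np.isfinite(y)):
        raise ValueError("all-NaN trace")
    if not (0 < min_prominence <= 1):
        raise ValueError("min_prominence must be in (0, 1]")
    if min_separation <= 0:
        raise ValueError("min_separation must be > 0 h")
    dt = trace.dt
    rng = float(y.max() - y.min())
    if rng > 0:
        idx, props = signal.find_peaks(
            y,
            prominence=min_prominence * rng,
            distance=max(1, int(round(min_separation / dt))),
        )
    else:
        idx = np.array([], dtype=int)
        props = {"prominences": np.array([]), "left_bases": np.array([], dtype=int)}

    t_peak1 = a_peak1 = t_peak2 = a_peak2 = onset_t1 = None
    if idx.size >= 1:
        i1 = idx[0]
        t_peak1 = float(trace.times[i1])
        a_peak1 = float(props["prominences"][0])
        base = float(y[i1]) - a_peak1
        thresh = base + rise_fraction * a_peak1
        lb = int(props["left_bases"][0])
        above = np.nonzero(y[lb : i1 + 1] >= thresh)[0]
        onset_t1 = float(trace.times[lb + above[0]]) if above.size else t_peak1
    if idx.size >= 2:
        i2 = idx[1]
        t_peak2, a_peak2 = float(trace.times[i2]), float(props["prominences"][1])

    n_tail = max(2, int(round(terminal_window / dt)) + 1)
    tail_t = trace.times[-n_tail:]
    tail_y = y[-n_tail:]
    terminal_slope = float(np.polyfit(tail_t, tail_y, 1)[0])

    return PeakFeatureRecord(
        cell_id=trace.cell_id,
        condition=trace.condition,
        n_peaks=int(idx.size),
        t_peak1=t_peak1,
        a_peak1=a_peak1,
        t_peak2=t_peak2,
        a_peak2=a_peak2,
        onset_t1=onset_t1,
        terminal_slope=terminal_slope,
    )


def features_frame(records: Iterable[PeakFeatureRecord]) -> pd.DataFrame:
    """Tabulate PeakFeatureRecords, one row per cell."""
    return pd.DataFrame([r.to_dict() for r in records])


@dataclass
class PopulationTrajectory:
    """Pointwise mean +/- sample SD trajectory of a group of cells."""

    group: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def as_trace(self) -> Trace:
        first = self.group.split("@")
        drug = first[0]
        dose = float(first[1]) if len(first) == 2 else float("nan")
        return Trace(
            cell_id=f"mean:{self.group}",
            drug=drug,
            dose=dose if np.isfinite(dose) else 0.0,
            batch="pooled",
            times=self.times,
            intensities=np.clip(self.mean, 0, None),
        )


def population_mean_trajectory(
    trace_set: TraceSet, group_by: str = "condition"
) -> dict[str, PopulationTrajectory]:
    """Per-group pointwise mean and sample SD (n-1 denominator)."""
    if len(trace_set) == 0:
        raise ValueError("empty trace set")
    out = {}
    for key, group in trace_set.groupby(group_by).items():
        mat = group.matrix()
        sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        out[key] = PopulationTrajectory(
            group=key, times=group.grid.copy(), mean=mat.mean(axis=0), sd=sd,
            n=mat.shape[0],
        )
    return out


def estimate_half_life(trace: Trace, fit_window: tuple[float, float] | None = None) -> float:
    """Half-life from a log-linear fit of intensity over the decay window.

    Fits log(intensity) against time by least squares inside ``fit_window``
    (whole trace by default) and returns ln(2) / |slope| in hours.  Raises if
    the fitted slope is non-negative (no decay) or intensities are not
    strictly positive inside the window.
    """
    t, y = trace.times, trace.intensities
    if fit_window is not None:
        lo, hi = fit_window
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if t.size < 3:
        raise ValueError("fit window contains fewer than 3 samples")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive inside the fit window")
    b = float(np.polyfit(t, np.log(y), 1)[0])
    if b >= 0:
        raise ValueError("no decay detected (non-negative log-linear slope)")
    return math.log(2.0) / (-b)


@dataclass
class ComparisonReport:
    """Two-group comparison of pulse features and cytokinesis timing.

    Fold-change is mean second-peak amplitude of B over A; time differences
    are A minus B in hours (positive = events earlier in B).  Each metric
    carries a Welch two-tailed t statistic and p-value; a metric whose data
    are absent in either group is reported as None, never as zero.
    """

    amplitude_fold_change: float | None
    amplitude_t: float | None
    amplitude_p: float | None
    peak2_time_diff_h: float | None
    peak2_time_t: float | None
    peak2_time_p: float | None
    cytokinesis_diff_h: float | None
    cytokinesis_t: float | None
    cytokinesis_p: float | None
    n_A: int
    n_B: int

    def to_json(self) -> str:
        entries = []
        for metric, value, t, p in [
            ("second_peak_amplitude_fold_B_over_A", self.amplitude_fold_change,
             self.amplitude_t, self.amplitude_p),
            ("median_second_peak_time_diff_A_minus_B_h", self.peak2_time_diff_h,
             self.peak2_time_t, self.peak2_time_p),
            ("median_first_cytokinesis_diff_A_minus_B_h", self.cytokinesis_diff_h,
             self.cytokinesis_t, self.cytokinesis_p),
        ]:
            entries.append(
                {"metric": metric, "value": value, "n_A": self.n_A,
                 "n_B": self.n_B, "statistic": t, "p": p}
            )
        return json.dumps(entries, indent=2)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float | None, float | None]:
    if a.size < 2 or b.size < 2:
        return None, None
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    features_a: Sequence[PeakFeatureRecord],
    features_b: Sequence[PeakFeatureRecord],
    cytokinesis_a: Sequence[Sequence[float]] = (),
    cytokinesis_b: Sequence[Sequence[float]] = (),
) -> ComparisonReport:
    """Compare pulse features of group B against reference group A."""
    if not features_a or not features_b:
        raise ValueError("both groups must be non-empty")

    a2_a = np.array([f.a_peak2 for f in features_a if f.a_peak2 is not None])
    a2_b = np.array([f.a_peak2 for f in features_b if f.a_peak2 is not None])
    t2_a = np.array([f.t_peak2 for f in features_a if f.t_peak2 is not None])
    t2_b = np.array([f.t_peak2 for f in features_b if f.t_peak2 is not None])
    cy_a = np.array([min(c) for c in cytokinesis_a if len(c)])
    cy_b = np.array([min(c) for c in cytokinesis_b if len(c)])

    fold = float(a2_b.mean() / a2_a.mean()) if a2_a.size and a2_b.size else None
    amp_t, amp_p = _welch(a2_a, a2_b) if fold is not None else (None, None)

    dt2 = float(np.median(t2_a) - np.median(t2_b)) if t2_a.size and t2_b.size else None
    t2_t, t2_p = _welch(t2_a, t2_b) if dt2 is not None else (None, None)

    dcy = float(np.median(cy_a) - np.median(cy_b)) if cy_a.size and cy_b.size else None
    cy_t, cy_p = _welch(cy_a, cy_b) if dcy is not None else (None, None)

    return ComparisonReport(
        amplitude_fold_change=fold, amplitude_t=amp_t, amplitude_p=amp_p,
        peak2_time_diff_h=dt2, peak2_time_t=t2_t, peak2_time_p=t2_p,
        cytokinesis_diff_h=dcy, cytokinesis_t=cy_t, cytokinesis_p=cy_p,
        n_A=len(features_a), n_B=len(features_b),
    )
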