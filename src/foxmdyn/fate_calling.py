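"""Rule-based classification of single-cell trajectories into six fates.

Each cell's trajectory shape maps to one phenotype: a delayed single pulse
that resolves means G1 arrest; a continuous rise held at the trace maximum
means G2 arrest; a delayed first pulse followed by a second means cell-cycle
delay; a much smaller first pulse relative to the second means cytokinesis
delay; sustained declining intensity means cell death; two pulses with an
on-schedule first pulse mean on-time cytokinesis.  "Delayed" is measured
against the median first-pulse time of the DMSO control, not an absolute
clock.  The rules form a fixed decision cascade (death > G2 arrest > G1
arrest > cell-cycle delay > cytokinesis delay > on-time); a trace matching
no rule is reported as ``unclassified``, never silently defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectories import PeakFeatureRecord, Trace

__all__ = [
    "FATE_LABELS",
    "UNCLASSIFIED",
    "FateRuleConfig",
    "reference_from_dmso",
    "classify_fate",
    "classify_set",
    "fate_distribution",
    "heatmap_order",
]

FATE_LABELS = (
    "on_time_cytokinesis",
    "cytokinesis_delay",
    "cell_cycle_delay",
    "g1_arrest",
    "g2_arrest",
    "cell_death",
)
UNCLASSIFIED = "unclassified"


@dataclass
class FateRuleConfig:
    """Thresholds of the fate decision cascade.

    ``ref_t_peak1``/``ref_t_peak2`` anchor "delayed" to the control medians.
    ``delay_margin`` (h) is how far past the control median the first pulse
    must sit to count as delayed; ``small_first_ratio`` is the first/second
    pulse height ratio below which the first pulse is "much smaller";
    ``death_slope`` (normalized intensity per hour) is the terminal slope
    below which a declining trace is dying; ``rise_end_fraction`` is the
    terminal level relative to the trace maximum above which the trace is a
    continuous rise; ``min_drop_fraction`` is the fraction of the pulse
    height the trace must shed for the pulse to count as resolved.
    """

    ref_t_peak1: float
    ref_t_peak2: float | None = None
    delay_margin: float = 2.0
    small_first_ratio: float = 0.5
    death_slope: float = -0.02
    rise_end_fraction: float = 0.8
    min_drop_fraction: float = 0.3
    terminal_level_window: float = 1.0

    def __post_init__(self) -> None:
        if self.delay_margin <= 0:
            raise ValueError("delay_margin must be > 0")
        for name in ("small_first_ratio", "rise_end_fraction", "min_drop_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def reference_from_dmso(
    dmso_features: Sequence[PeakFeatureRecord], **overrides
) -> FateRuleConfig:
    """Build the rule config anchored at the DMSO median pulse times."""
    with_peak = [f for f in dmso_features if f.t_peak1 is not None]
    if len(with_peak) < 10:
        raise ValueError(
            f"need >= 10 control cells with a detected first peak, got {len(with_peak)}"
        )
    ref1 = float(np.median([f.t_peak1 for f in with_peak]))
    t2s = [f.t_peak2 for f in with_peak if f.t_peak2 is not None]
    ref2 = float(np.median(t2s)) if t2s else None
    return FateRuleConfig(ref_t_peak1=ref1, ref_t_peak2=ref2, **overrides)


def classify_fate(
    features: PeakFeatureRecord, trace: Trace, rules: FateRuleConfig
) -> str:
    """Deterministic fate call for one cell.

    The cascade is evaluated in a fixed order so that a trace meeting several
    qualitative descriptions receives one reproducible label.
    """
    if features is None:
        raise ValueError("missing features")
    y = trace.intensities
    trace_max = float(y.max())
    n_tail = max(1, int(round(rules.terminal_level_window / trace.dt)) + 1)
    terminal_level = float(y[-n_tail:].mean())
    delayed = (
        features.t_peak1 is not None
        and features.t_peak1 > rules.ref_t_peak1 + rules.delay_margin
    )

    # 1. sustained decline to a low terminal level
    if features.terminal_slope < rules.death_slope and terminal_level < 0.5 * trace_max:
        return "cell_death"

    # 2. continuous rise held at the maximum
    if trace_max > 0 and terminal_level >= rules.rise_end_fraction * trace_max:
        return "g2_arrest"

    # 3. delayed single resolved pulse
    if features.n_peaks == 1 and delayed and features.a_peak1:
        i1 = int(np.argmin(np.abs(trace.times - features.t_peak1)))
        drop = (float(y[i1]) - float(y[i1:].min())) / features.a_peak1
        if drop >= rules.min_drop_fraction:
            return "g1_arrest"

    # 4. delayed first pulse with a later second pulse
    if features.n_peaks >= 2 and delayed:
        return "cell_cycle_delay"

    # 5. much smaller first pulse
    if (
        features.n_peaks >= 2
        and features.a_peak1 is not None
        and features.a_peak2
        and features.a_peak1 / features.a_peak2 < rules.small_first_ratio
    ):
        return "cytokinesis_delay"

    # 6. two pulses, first on schedule
    if features.n_peaks >= 2 and not delayed:
        return "on_time_cytokinesis"

    return UNCLASSIFIED


def classify_set(
    traces: Sequence[Trace],
    features: Sequence[PeakFeatureRecord],
    rules: FateRuleConfig,
) -> pd.DataFrame:
    """Classify a set of cells; returns cell_id, condition, label, t_peak1."""
    if len(traces) != len(features):
        raise ValueError("traces and features must align")
    rows = []
    for tr, f in zip(traces, features):
        rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition,
                "label": classify_fate(f, tr, rules),
                "t_peak1": f.t_peak1,
                "truth_label": tr.truth_label,
            }
        )
    return pd.DataFrame(rows)


def fate_distribution(
    labels: pd.DataFrame, group_by: str = "condition"
) -> pd.DataFrame:
    """Per-group fractions over the six fates plus the unclassified tally."""
    all_labels = FATE_LABELS + (UNCLASSIFIED,)
    rows = []
    for key, g in labels.groupby(group_by, sort=True):
        n = len(g)
        if n == 0:
            continue
        counts = g["label"].value_counts()
        row = {group_by: key, "n": n}
        for lb in all_labels:
            row[f"frac_{lb}"] = int(counts.get(lb, 0)) / n
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_order(labels: pd.DataFrame) -> list[str]:
    """Cell ids ordered by fate label then first-pulse time, for heatmaps."""
    rank = {lb: i for i, lb in enumerate(FATE_LABELS + (UNCLASSIFIED,))}
    df = labels.copy()
    df["_rank"] = df["label"].map(rank)
    df["_t"] = df["t_peak1"].fillna(np.inf)
    return df.sort_values(["_rank", "_t", "cell_id"])["cell_id"].tolist()
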