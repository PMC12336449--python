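"""End-to-end panel dynamics analysis.

The condition-level workflow behind the six-cluster result: normalize traces
to the initial per-condition mean, remove batch location/scale effects with
ComBat, average the adjusted trajectories into one mean curve per
drug x batch, fit functional PCA to those mean curves, average each drug's
per-batch score vectors into one drug-level score vector, and cluster the
drugs by mutual-KNN components of the score-correlation matrix.

fPCA is fit on condition-mean curves rather than single cells because the
condition-level analysis targets between-condition structure; cell-level
noise modes otherwise absorb a sizeable share of the variance.  Cell-level
fPCA is still available directly through :func:`foxmdyn.fpca.fit_fpca`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusterResult, knn_cluster, score_similarity
from .fpca import BatchModel, FPCAModel, combat_adjust, fit_fpca
from .trajectories import TraceSet, normalize_to_initial_mean

__all__ = ["PanelAnalysis", "analyze_panel", "PANEL_N_CELLS"]

#: Cells per condition x batch used by the default panel-level analyses.
#: Realized archetype fractions are multinomially noisy; at ~400 cells per
#: drug the between-condition structure dominates that sampling noise.
PANEL_N_CELLS = 200


@dataclass
class PanelAnalysis:
    """Result bundle of the condition-level panel analysis."""

    model: FPCAModel                 # fPCA of the drug x batch mean curves
    batch_model: BatchModel
    curve_keys: list[tuple[str, str]]    # (drug, batch) per mean curve
    mean_curves: np.ndarray              # (n_curves, n_timepoints)
    drugs: list[str]
    drug_scores: np.ndarray              # (n_drugs, K) mean score vectors
    similarity: np.ndarray
    clusters: ClusterResult

    @property
    def fve2(self) -> float:
        """Cumulative variance fraction of the first two components."""
        return float(self.model.var_fraction[:2].sum())


def analyze_panel(
    traces: TraceSet,
    k_neighbors: int = 2,
    exclude_drugs: tuple[str, ...] = ("DMSO",),
    normalize_window: int = 6,
    fve: float = 0.99,
) -> PanelAnalysis:
    """Run the condition-level dynamics analysis on a two-batch panel.

    ``exclude_drugs`` removes control conditions from the clustered item set
    (the control is analysed separately from the inhibitors); pass ``()`` to
    cluster every drug present.
    """
    if len(traces) == 0:
        raise ValueError("empty trace set")
    norm = normalize_to_initial_mean(traces, window_frames=normalize_window)
    adjusted, batch_model = combat_adjust(
        norm.matrix(), [tr.batch for tr in norm]
    )

    groups: dict[tuple[str, str], list[int]] = {}
    for i, tr in enumerate(norm):
        groups.setdefault((tr.drug, tr.batch), []).append(i)
    curve_keys = list(groups)
    mean_curves = np.vstack([adjusted[groups[k]].mean(axis=0) for k in curve_keys])

    model = fit_fpca(mean_curves, traces.grid, fve=fve)

    drugs: list[str] = []
    for drug, _ in curve_keys:
        if drug not in drugs and drug not in exclude_drugs:
            drugs.append(drug)
    if len(drugs) < 2:
        raise ValueError("need >= 2 non-excluded drugs to cluster")
    drug_scores = np.vstack(
        [
            model.scores[[i for i, k in enumerate(curve_keys) if k[0] == d]].mean(axis=0)
            for d in drugs
        ]
    )

    similarity, _ = score_similarity(drug_scores)
    clusters = knn_cluster(similarity, k_neighbors, items=drugs)

    return PanelAnalysis(
        model=model,
        batch_model=batch_model,
        curve_keys=curve_keys,
        mean_curves=mean_curves,
        drugs=drugs,
        drug_scores=drug_scores,
        similarity=similarity,
        clusters=clusters,
    )
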