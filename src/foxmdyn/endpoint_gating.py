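"""Endpoint DAPI/EdU cell-cycle gating.

EdU marks cells that replicated DNA before fixation; integrated DAPI is a
proxy for DNA content (2N vs 4N).  Both stain distributions across a pooled
population are bimodal, so each cutoff is derived by fitting a two-component
Gaussian mixture to log intensities and taking the point between the
component means where the posterior responsibility is 0.5.  The two cutoffs
segment cells into four phases:

=========  =====  =====
phase      DAPI   EdU
=========  =====  =====
G1         low    low
early S    low    high
late S     high   high
G2/M       high   low
=========  =====  =====

Cells exactly on a cutoff go to the "low" side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

__all__ = [
    "GateSet",
    "bimodal_cutoff",
    "fit_gates",
    "gate_cells",
    "phase_distribution",
    "otsu_cutoff",
]

PHASES = ("G1", "early_S", "late_S", "G2_M")


@dataclass
class GateFit:
    """One fitted bimodal cutoff with its mixture parameters (log domain)."""

    cutoff: float               # original intensity scale
    log_cutoff: float
    log_means: tuple[float, float]
    log_sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float


@dataclass
class GateSet:
    """EdU and DAPI cutoffs used for four-phase gating."""

    edu: GateFit
    dapi: GateFit

    @property
    def edu_cutoff(self) -> float:
        return self.edu.cutoff

    @property
    def dapi_cutoff(self) -> float:
        return self.dapi.cutoff

    def to_json(self) -> str:
        def enc(g: GateFit) -> dict:
            return {
                "cutoff": g.cutoff, "log_cutoff": g.log_cutoff,
                "log_means": list(g.log_means), "log_sds": list(g.log_sds),
                "weights": list(g.weights), "log_likelihood": g.log_likelihood,
            }
        return json.dumps({"edu": enc(self.edu), "dapi": enc(self.dapi)}, indent=2)


def bimodal_cutoff(
    values: np.ndarray,
    n_restarts: int = 10,
    tol: float = 1e-8,
    seed: int = 0,
    min_weight: float = 0.01,
    min_mean_separation: float = 0.1,
) -> GateFit:
    """Fit a two-component Gaussian mixture to log intensities and cut at
    equal posterior responsibility.

    Values are pooled across all treatment conditions before fitting.  Raises
    "no bimodality detected" if the fit degenerates (a component weight below
    ``min_weight`` or log-means closer than ``min_mean_separation``).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError("need >= 50 values to fit a bimodal cutoff")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    logx = np.log(x).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, n_init=n_restarts, tol=tol, random_state=seed,
        covariance_type="full", reg_covar=1e-10,
    ).fit(logx)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    s_lo, s_hi = sds[order]
    w_lo, w_hi = weights[order]
    if min(w_lo, w_hi) < min_weight or (m_hi - m_lo) < min_mean_separation:
        raise ValueError("no bimodality detected")

    def resp_diff(z: float) -> float:
        # posterior(high component) - 0.5 at log intensity z, computed in
        # log space so near-degenerate components cannot underflow to 0/0
        from scipy.special import expit
        from scipy.stats import norm
        lp_hi = math.log(w_hi) + norm.logpdf(z, m_hi, s_hi)
        lp_lo = math.log(w_lo) + norm.logpdf(z, m_lo, s_lo)
        return expit(lp_hi - lp_lo) - 0.5

    lo, hi = m_lo, m_hi
    # The responsibility is monotone between the means for well-separated
    # fits; nudge inwards if an endpoint does not bracket the root.
    f_lo, f_hi = resp_diff(lo), resp_diff(hi)
    if f_lo > 0 or f_hi < 0:
        log_cut = (m_lo + m_hi) / 2.0
    else:
        log_cut = brentq(resp_diff, lo, hi, xtol=1e-12)
    return GateFit(
        cutoff=float(np.exp(log_cut)), log_cutoff=float(log_cut),
        log_means=(float(m_lo), float(m_hi)), log_sds=(float(s_lo), float(s_hi)),
        weights=(float(w_lo), float(w_hi)),
        log_likelihood=float(gm.score(logx) * logx.size),
    )


def otsu_cutoff(values: np.ndarray, n_bins: int = 256) -> float:
    """Histogram-threshold fallback (maximal between-class variance) on log
    intensities, for populations where the mixture fit degenerates."""
    logx = np.log(np.asarray(values, dtype=float))
    hist, edges = np.histogram(logx, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    best, best_t = -1.0, centers[n_bins // 2]
    w0 = 0.0
    sum0 = 0.0
    sum_all = (hist * centers).sum()
    for i in range(n_bins - 1):
        w0 += hist[i]
        sum0 += hist[i] * centers[i]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum0 / w0
        m1 = (sum_all - sum0) / w1
        between = w0 * w1 * (m0 - m1) ** 2
        if between > best:
            best, best_t = between, (centers[i] + centers[i + 1]) / 2.0
    return float(np.exp(best_t))


def fit_gates(stains: pd.DataFrame, seed: int = 0) -> GateSet:
    """Fit EdU then DAPI cutoffs on intensities pooled across conditions."""
    return GateSet(
        edu=bimodal_cutoff(stains["edu"].to_numpy(), seed=seed),
        dapi=bimodal_cutoff(stains["dapi"].to_numpy(), seed=seed),
    )


def gate_cells(stains: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Assign each cell a phase label by the 2x2 cutoff rule.

    Returns a copy of the table with a ``phase`` column; cells with a missing
    intensity are excluded and tallied in the frame's ``attrs['n_excluded']``.
    """
    df = stains.copy()
    ok = df["dapi"].notna() & df["edu"].notna()
    excluded = int((~ok).sum())
    df = df[ok].copy()
    dapi_high = df["dapi"].to_numpy() > gates.dapi_cutoff
    edu_high = df["edu"].to_numpy() > gates.edu_cutoff
    phase = np.where(
        dapi_high,
        np.where(edu_high, "late_S", "G2_M"),
        np.where(edu_high, "early_S", "G1"),
    )
    df["phase"] = phase
    df.attrs["n_excluded"] = excluded
    return df


def phase_distribution(
    labelled: pd.DataFrame, group_by: str = "condition"
) -> pd.DataFrame:
    """Per-group phase fractions (summing to 1) with counts alongside."""
    if "phase" not in labelled.columns:
        raise ValueError("stains must be gated first (no 'phase' column)")
    rows = []
    for key, g in labelled.groupby(group_by, sort=True):
        n = len(g)
        if n == 0:
            continue
        counts = g["phase"].value_counts()
        row = {group_by: key, "n": n}
        for p in PHASES:
            c = int(counts.get(p, 0))
            row[f"frac_{p}"] = c / n
            row[f"n_{p}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
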