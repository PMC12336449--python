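"""Batch correction and functional principal component analysis.

Trajectories sampled densely on a uniform grid are treated as discretized
curves.  :func:`combat_adjust` removes per-batch location/scale effects at
every time point with the parametric empirical-Bayes procedure (normal prior
on batch locations, inverse-gamma on batch scales, moment-matched
hyperparameters, iterative conditional estimation).  :func:`fit_fpca`
eigen-decomposes the quadrature-weighted sample covariance operator of the
curves: weighting the centered data by the square root of the trapezoid
weights maps discrete eigenvectors to eigenfunctions orthonormal under the
quadrature inner product, so scores are plain quadrature integrals of the
centered curves against the eigenfunctions.

No presmoothing is applied by default: at 10-min sampling over 48 h the grid
is dense enough that the raw sample covariance is already a stable estimate
of the covariance surface.  An optional moving-average presmooth is available
through :func:`foxmdyn.trajectories.smooth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BatchModel",
    "FPCAModel",
    "combat_adjust",
    "fit_fpca",
    "variance_explained",
    "reconstruct",
    "project",
]


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch location/scale model."""

    batch_levels: list[str]
    stand_mean: np.ndarray          # alpha_j, per time point
    pooled_var: np.ndarray          # sigma_j^2, per time point
    gamma_hat: np.ndarray           # raw batch locations, (n_batch, p)
    delta2_hat: np.ndarray          # raw batch scales (variances), (n_batch, p)
    gamma_star: np.ndarray          # shrunken locations
    delta2_star: np.ndarray         # shrunken scales
    passthrough: np.ndarray         # boolean mask of unadjusted time points


def _shrink_batch(
    z_b: np.ndarray, g_hat: np.ndarray, d2_hat: np.ndarray, tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional EB estimates for one batch.

    Normal prior on locations (moment-matched mean/variance across time
    points) and inverse-gamma prior on scales (moment-matched shape/rate).
    """
    n_b = z_b.shape[0]
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1)
    m = d2_hat.mean()
    v = d2_hat.var(ddof=1)
    if v <= 0:
        # Degenerate prior: no shrinkage possible on scales.
        a_prior, b_prior = 2.0, m
    else:
        a_prior = (2.0 * v + m * m) / v
        b_prior = (m * v + m ** 3) / v

    g_star = g_hat.copy()
    d2_star = d2_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * t2 * g_hat + d2_star * g_bar) / (n_b * t2 + d2_star)
        sse = ((z_b - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * sse + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
            np.max(np.abs(d2_new - d2_star) / (np.abs(d2_star) + 1e-12)),
        )
        g_star, d2_star = g_new, d2_new
        if change < tol:
            break
    return g_star, d2_star


def combat_adjust(
    matrix: np.ndarray, batches, tol: float = 1e-6
) -> tuple[np.ndarray, BatchModel]:
    """Remove batch location/scale effects from a traces x timepoints matrix.

    Returns the adjusted matrix (same shape) and the fitted
    :class:`BatchModel`.  Time points with zero pooled variance are passed
    through unadjusted with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (traces x timepoints)")
    batches = np.asarray([str(b) for b in batches])
    if batches.shape[0] != X.shape[0]:
        raise ValueError("one batch label per trace required")
    levels = sorted(set(batches))
    if len(levels) < 2:
        raise ValueError("combat requires >= 2 batches")
    masks = {b: batches == b for b in levels}
    for b, mask in masks.items():
        if mask.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 traces")

    n, p = X.shape
    batch_means = np.vstack([X[masks[b]].mean(axis=0) for b in levels])
    sizes = np.array([masks[b].sum() for b in levels], dtype=float)
    stand_mean = (sizes[:, None] * batch_means).sum(axis=0) / n
    resid = X - np.vstack([batch_means[levels.index(b)] for b in batches])
    pooled_var = (resid ** 2).sum(axis=0) / n

    passthrough = pooled_var <= 0
    if passthrough.any():
        warnings.warn(
            f"{int(passthrough.sum())} constant time point(s) passed through unadjusted"
        )
    sigma = np.sqrt(np.where(passthrough, 1.0, pooled_var))

    Z = (X - stand_mean[None, :]) / sigma[None, :]
    gamma_hat = np.vstack([Z[masks[b]].mean(axis=0) for b in levels])
    # ddof=0 matches the pooled-variance denominator, so two batches holding
    # identical data yield delta2_hat = 1 exactly and adjustment is a no-op
    delta2_hat = np.vstack([Z[masks[b]].var(axis=0, ddof=0) for b in levels])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i, b in enumerate(levels):
        gamma_star[i], delta2_star[i] = _shrink_batch(
            Z[masks[b]], gamma_hat[i], delta2_hat[i], tol=tol
        )

    adjusted = X.copy()
    for i, b in enumerate(levels):
        zb = (Z[masks[b]] - gamma_star[i][None, :]) / np.sqrt(delta2_star[i])[None, :]
        adjusted[masks[b]] = zb * sigma[None, :] + stand_mean[None, :]
    adjusted[:, passthrough] = X[:, passthrough]

    model = BatchModel(
        batch_levels=levels, stand_mean=stand_mean, pooled_var=pooled_var,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star, passthrough=passthrough,
    )
    return adjusted, model


# ---------------------------------------------------------------------------
# fPCA
# ---------------------------------------------------------------------------


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for a uniform grid."""
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    w = np.full(grid.size, dt)
    w[0] = w[-1] = dt / 2.0
    return w


@dataclass
class FPCAModel:
    """Fitted functional PCA decomposition.

    ``eigenfunctions`` has shape (K, n_timepoints) and is orthonormal under
    the trapezoid quadrature inner product; ``scores`` has shape
    (n_traces, K); ``eigenvalues`` are the score variances, descending.
    """

    grid: np.ndarray
    weights: np.ndarray
    mean_fn: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    var_fraction: np.ndarray
    K_selected: int


def _fix_signs(phi: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Orient each eigenfunction so its quadrature integral is >= 0.

    Ties (integral numerically zero) are broken by requiring the value at
    the final time point to be >= 0.
    """
    phi = phi.copy()
    integrals = phi @ w
    scale = np.abs(phi).max(axis=1) * w.sum()
    for k in range(phi.shape[0]):
        tol = 1e-10 * max(scale[k], 1.0)
        if integrals[k] < -tol or (abs(integrals[k]) <= tol and phi[k, -1] < 0):
            phi[k] = -phi[k]
    return phi


def fit_fpca(
    matrix: np.ndarray,
    grid: np.ndarray,
    n_components: int | None = None,
    fve: float = 0.99,
) -> FPCAModel:
    """Fit fPCA to a traces x timepoints matrix on a uniform grid.

    The centered data are weighted by the square root of the trapezoid
    weights and decomposed by SVD; eigenvalues below numerical rank are
    dropped (negative eigenvalues cannot occur under SVD; any numerically
    negative eigenvalue of the covariance operator is clipped at zero).
    ``K_selected`` is the smallest K whose cumulative variance fraction
    reaches ``fve``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("fpca requires a 2-D matrix with >= 3 traces")
    grid = np.asarray(grid, dtype=float)
    if grid.size != X.shape[1]:
        raise ValueError("grid length must match number of time points")
    steps = np.diff(grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
        raise ValueError("grid must be uniform increasing")

    n, p = X.shape
    w = trapezoid_weights(grid)
    mean_fn = X.mean(axis=0)
    Xc = X - mean_fn[None, :]
    B = Xc * np.sqrt(w)[None, :] / np.sqrt(n - 1)
    _, s, vt = np.linalg.svd(B, full_matrices=False)
    lam = np.clip(s * s, 0.0, None)
    total = lam.sum()
    keep = lam > max(lam[0], 0.0) * 1e-12 if total > 0 else np.zeros_like(lam, bool)
    lam = lam[keep]
    u = vt[keep]

    K_avail = lam.size
    if n_components is not None and n_components > K_avail:
        warnings.warn(
            f"requested {n_components} components, only {K_avail} available; truncating"
        )
    K = K_avail if n_components is None else min(n_components, K_avail)
    lam = lam[:K]
    u = u[:K]

    phi = u / np.sqrt(w)[None, :]
    phi = _fix_signs(phi, w)
    scores = Xc @ (phi * w[None, :]).T
    var_fraction = lam / total if total > 0 else np.zeros_like(lam)

    cum = np.cumsum(var_fraction)
    k_sel = int(np.searchsorted(cum, fve) + 1)
    k_sel = min(k_sel, K)

    return FPCAModel(
        grid=grid, weights=w, mean_fn=mean_fn, eigenfunctions=phi,
        eigenvalues=lam, scores=scores, var_fraction=var_fraction,
        K_selected=k_sel,
    )


def variance_explained(model: FPCAModel, k: int) -> float:
    """Cumulative variance fraction of the first k components."""
    if not 1 <= k <= model.eigenvalues.size:
        raise ValueError(f"k must be in [1, {model.eigenvalues.size}]")
    return float(model.var_fraction[:k].sum())


def reconstruct(model: FPCAModel, K: int | None = None) -> np.ndarray:
    """Reconstruct the data matrix from the first K components."""
    K = model.eigenvalues.size if K is None else K
    if not 1 <= K <= model.eigenvalues.size:
        raise ValueError("K out of range")
    return model.mean_fn[None, :] + model.scores[:, :K] @ model.eigenfunctions[:K]


def project(model: FPCAModel, curve: np.ndarray) -> np.ndarray:
    """Score a new curve (or stack of curves) against the fitted model."""
    x = np.atleast_2d(np.asarray(curve, dtype=float))
    if x.shape[1] != model.grid.size:
        raise ValueError("curve length must match the model grid")
    sc = (x - model.mean_fn[None, :]) @ (model.eigenfunctions * model.weights[None, :]).T
    return sc[0] if np.asarray(curve).ndim == 1 else sc
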