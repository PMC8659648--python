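"""Geometry-based (nonlinear) intrinsic-dimension estimators.

These estimators read the intrinsic dimensionality off local geometric
properties of the point cloud — how neighborhood counts grow with radius
(Correlation Dimension), the likelihood of nearest-neighbor distances
(Levina-Bickel MLE), the distribution of second-to-first neighbor distance
ratios (Two Nearest Neighbors), and the probability that a point is Fisher
separable from the rest (Fisher Separability Analysis).  Unlike PCA-based
methods they make no global linear-model assumption, so they remain valid
for nonlinearly embedded manifolds.

All distances are Euclidean; exact duplicate points are removed (with a
recorded count) before any neighbor computation, since zero distances break
the log-based statistics.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from .linear import DimensionEstimate, MatrixLike, as_samples

__all__ = [
    "correlation_dimension",
    "lbmle",
    "two_nn",
    "fisher_separability_dimension",
    "kneighbor_distances",
    "drop_duplicate_points",
]

logger = logging.getLogger(__name__)


def drop_duplicate_points(samples: np.ndarray) -> Tuple[np.ndarray, int]:
    """Remove exact duplicate rows; returns (unique rows, #removed).

    Order of first occurrence is preserved so results stay deterministic.
    """
    _, idx = np.unique(samples, axis=0, return_index=True)
    keep = np.sort(idx)
    removed = samples.shape[0] - keep.size
    if removed:
        logger.info("removed %d duplicate points before neighbor analysis", removed)
    return samples[keep], removed


def kneighbor_distances(samples: np.ndarray, k: int) -> np.ndarray:
    """``M x k`` matrix of sorted distances to the k nearest neighbors
    (self excluded).  Input must already be duplicate-free."""
    M = samples.shape[0]
    if k >= M:
        raise ValueError(f"k={k} must be < number of points ({M})")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(samples)
    dist, _ = nn.kneighbors(samples)
    return dist[:, 1:]


# ---------------------------------------------------------------------------
# Correlation Dimension
# ---------------------------------------------------------------------------

def correlation_dimension(
    data: MatrixLike,
    n_radii: int = 32,
    fit_range: Tuple[float, float] = (2.0, 25.0),
) -> DimensionEstimate:
    """Grassberger-Procaccia correlation dimension.

    The correlation integral ``C(r) = 2/(M(M-1)) * #{i<j : d_ij < r}`` is
    evaluated on ``n_radii`` log-spaced radii between the 1st and 99th
    percentiles of the pairwise distances; the estimate is the least-squares
    slope of ``log C(r)`` versus ``log r`` over the radii lying between the
    ``fit_range`` percentiles of pairwise distance.  The default 2nd-25th
    percentile band stays below the saturation shoulder of the curve;
    wider/higher bands bias the slope low on compact manifolds.
    """
    samples = as_samples(data)
    samples, _ = drop_duplicate_points(samples)
    M = samples.shape[0]
    if M < 100:
        raise ValueError(f"correlation dimension needs M >= 100 unique points, got {M}")
    d_ij = pdist(samples)
    if d_ij.max() == 0:
        raise ValueError("all points identical: correlation integral undefined")
    r_lo, r_hi = np.percentile(d_ij, [1.0, 99.0])
    radii = np.geomspace(max(r_lo, 1e-12 * r_hi), r_hi, n_radii)
    # C(r) via a single sort instead of n_radii full passes
    d_sorted = np.sort(d_ij)
    counts = np.searchsorted(d_sorted, radii, side="left")
    C = counts / d_ij.size

    lo_p, hi_p = fit_range
    fit_lo, fit_hi = np.percentile(d_ij, [lo_p, hi_p])
    mask = (radii >= fit_lo) & (radii <= fit_hi) & (C > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 radii with nonzero counts inside the fit range "
            f"({lo_p}-{hi_p} pct); widen fit_range or add data"
        )
    slope = np.polyfit(np.log(radii[mask]), np.log(C[mask]), 1)[0]
    return DimensionEstimate(
        value=float(slope),
        method="CD",
        params={"n_radii": n_radii, "fit_range": tuple(fit_range)},
    )


# ---------------------------------------------------------------------------
# Levina-Bickel maximum likelihood
# ---------------------------------------------------------------------------

def lbmle(
    data: MatrixLike,
    k1: int = 10,
    k2: int = 20,
    mackay_correction: bool = False,
) -> DimensionEstimate:
    """Levina-Bickel maximum-likelihood intrinsic dimension.

    For each point ``i`` and neighbor count ``k``, the local estimate is

        m_k(i) = [ (1/(k-1)) * sum_{j<k} ln( T_k(i) / T_j(i) ) ]^{-1}

    with ``T_j(i)`` the distance to the j-th nearest neighbor.  Per-k
    estimates average ``m_k(i)`` over points; the final value averages over
    ``k in [k1, k2]``.  With ``mackay_correction`` the per-k aggregation is
    the inverse of the mean inverse (harmonic-style average), the correction
    suggested by MacKay and Ghahramani.
    """
    samples = as_samples(data)
    samples, removed = drop_duplicate_points(samples)
    M = samples.shape[0]
    if not (2 <= k1 < k2):
        raise ValueError(f"require k2 > k1 >= 2, got k1={k1}, k2={k2}")
    if M <= k2 + 1:
        raise ValueError(f"need more than k2+1={k2 + 1} unique points, got {M}")
    if removed > 0.01 * (M + removed):
        warnings.warn(
            f"{removed} duplicate points (> 1%) removed before LBMLE",
            stacklevel=2,
        )
    dist = kneighbor_distances(samples, k2)  # M x k2, strictly positive
    log_d = np.log(dist)
    per_k = np.empty(k2 - k1 + 1)
    for idx, k in enumerate(range(k1, k2 + 1)):
        # mean over j of log(T_k) - log(T_j), j = 1..k-1
        inv_m = log_d[:, k - 1, None] - log_d[:, : k - 1]
        inv_m = inv_m.mean(axis=1)
        m_hat = 1.0 / inv_m
        per_k[idx] = 1.0 / np.mean(inv_m) if mackay_correction else np.mean(m_hat)
    return DimensionEstimate(
        value=float(per_k.mean()),
        method="LBMLE",
        params={"k1": k1, "k2": k2, "mackay_correction": mackay_correction,
                "duplicates_removed": removed},
    )


# ---------------------------------------------------------------------------
# Two Nearest Neighbors
# ---------------------------------------------------------------------------

def two_nn(data: MatrixLike, discard_fraction: float = 0.10) -> DimensionEstimate:
    """Two-nearest-neighbors estimator of Facco et al.

    For each point the ratio ``mu = r2/r1`` of second- to first-neighbor
    distance follows ``F(mu) = 1 - mu^{-d}`` on a uniform d-dimensional
    manifold, so ``d`` is the slope of the origin-constrained regression of
    ``-ln(1 - F)`` on ``ln mu`` over the empirical CDF.  The top
    ``discard_fraction`` of ratios (default 10%) is discarded to damp the
    heavy tail.
    """
    if not 0 <= discard_fraction < 0.5:
        raise ValueError(f"discard_fraction must be in [0, 0.5), got {discard_fraction}")
    samples = as_samples(data)
    samples, _ = drop_duplicate_points(samples)
    M = samples.shape[0]
    if M < 100:
        raise ValueError(f"two_nn needs M >= 100 unique points, got {M}")
    dist = kneighbor_distances(samples, 2)
    mu = dist[:, 1] / dist[:, 0]
    mu = np.sort(mu)
    F = np.arange(1, M + 1) / M
    n_keep = M - max(int(np.floor(discard_fraction * M)), 1)  # F=1 point must go
    x = np.log(mu[:n_keep])
    y = -np.log1p(-F[:n_keep])
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise ValueError(
            "degenerate neighbor-distance ratios (all mu equal): slope undefined"
        )
    slope = float(np.dot(x, y) / sxx)
    return DimensionEstimate(
        value=slope, method="TNN", params={"discard_fraction": discard_fraction}
    )


# ---------------------------------------------------------------------------
# Fisher Separability Analysis
# ---------------------------------------------------------------------------

def _fsa_inseparability(d: float, alpha_sep: float, calibration: str = "sphere") -> float:
    """Mean inseparability probability at threshold ``alpha_sep`` for a
    point cloud of dimension ``d``:

        p(a, d) ~ (1 - a^2)^(e/2) / (a * sqrt(2*pi*d))

    with exponent ``e = d - 1`` under the ``"sphere"`` calibration (the cap
    measure of S^{d-1}, consistent with the sphere projection applied during
    preprocessing) and ``e = d + 1`` under ``"ball"`` (the uniform-unit-ball
    bound of the original method).  Inverting the ball variant against
    sphere-projected points biases the estimate low — the documented slight
    underestimation of the original estimator — so ``"sphere"`` is the
    default.  Sanity anchors for the sphere form: d=1 gives p = 1/2 exactly
    (antipodal points), and brute-force pair counts on uniform spheres match
    for moderate d.
    """
    e = (d - 1) if calibration == "sphere" else (d + 1)
    return (1 - alpha_sep**2) ** (e / 2.0) / (alpha_sep * np.sqrt(2 * np.pi * d))


def fisher_separability_dimension(
    data: MatrixLike,
    alpha_sep: float = 0.8,
    pre_pca_threshold: Optional[float] = None,
    calibration: str = "sphere",
) -> DimensionEstimate:
    """Fisher Separability Analysis intrinsic dimension.

    The data are centered, projected onto the principal components that each
    explain at least ``pre_pca_threshold`` of the variance (default
    ``1/(2N)``), whitened, and projected to the unit sphere.  A point ``x``
    is Fisher-separable from ``y`` at threshold ``alpha_sep`` iff
    ``<x, y> <= alpha_sep * <x, x>``.  The mean probability ``p`` that a
    point fails to separate from another is matched to the closed-form
    uniform-sphere relation to recover ``d`` by 1-D root finding.

    If every point separates from every other (``p = 0``) the relation
    cannot be inverted; the projection rank is returned with an
    ``estimate_saturated`` flag in ``params``.

    ``calibration`` selects the closed-form relation: ``"sphere"``
    (default, consistent with the sphere projection) or ``"ball"`` (the
    original method's uniform-ball bound, which runs a little low).
    """
    if calibration not in ("sphere", "ball"):
        raise ValueError(f"calibration must be 'sphere' or 'ball', got {calibration!r}")
    if not 0 < alpha_sep < 1:
        raise ValueError(f"alpha_sep must be in (0, 1), got {alpha_sep}")
    samples = as_samples(data)
    samples, _ = drop_duplicate_points(samples)
    M, N = samples.shape
    if M < 100:
        raise ValueError(f"FSA needs M >= 100 unique points, got {M}")
    if pre_pca_threshold is None:
        pre_pca_threshold = 1.0 / (2 * N)

    centered = samples - samples.mean(axis=0)
    cov = centered.T @ centered / (M - 1)
    ev, vec = np.linalg.eigh(cov)
    ev, vec = ev[::-1], vec[:, ::-1]
    total = ev.sum()
    if total <= 0:
        raise ValueError("zero-variance data: FSA undefined")
    keep = ev / total >= pre_pca_threshold
    rank = max(int(keep.sum()), 1)
    proj = centered @ vec[:, :rank] / np.sqrt(ev[:rank])  # whitened scores
    norms = np.linalg.norm(proj, axis=1)
    nz = norms > 0
    proj = proj[nz] / norms[nz, None]  # unit sphere
    m = proj.shape[0]

    gram = proj @ proj.T
    np.fill_diagonal(gram, -np.inf)
    violations = np.count_nonzero(gram > alpha_sep, axis=1)
    p_bar = float(violations.sum() / (m * (m - 1)))

    if p_bar >= 1.0:
        raise ValueError("all point pairs inseparable: FSA cannot invert")
    if p_bar == 0.0:
        return DimensionEstimate(
            value=float(rank),
            method="FSA",
            params={"alpha_sep": alpha_sep, "estimate_saturated": True,
                    "projection_rank": rank},
        )

    def f(d: float) -> float:
        # underflow of the cap probability at huge d is expected: -inf log
        # just tells the bracketing search the root lies far to the left
        with np.errstate(divide="ignore"):
            return np.log(_fsa_inseparability(d, alpha_sep, calibration)) - np.log(p_bar)

    d_lo, d_hi = 1e-3, 1e5
    if f(d_lo) < 0:  # even d -> 0 gives too little inseparability
        d_est = d_lo
    elif f(d_hi) > 0:
        d_est = float(rank)
    else:
        d_est = float(brentq(f, d_lo, d_hi, xtol=1e-9))
    return DimensionEstimate(
        value=max(d_est, 1e-3),
        method="FSA",
        params={"alpha_sep": alpha_sep, "p_inseparable": p_bar,
                "projection_rank": rank, "calibration": calibration},
    )
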