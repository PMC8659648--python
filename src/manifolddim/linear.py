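"""PCA-based (linear) dimensionality estimators.

All three estimators operate on the eigenvalue spectrum of the sample
covariance of the data: a cumulative-variance cutoff, the Participation
Ratio ``PR = (sum lambda)^2 / sum lambda^2``, and Parallel Analysis, which
counts eigenvalues exceeding a shuffle-based null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Union

import numpy as np

from .simulate import ChannelMatrix

__all__ = [
    "EigenSpectrum",
    "DimensionEstimate",
    "eigen_spectrum",
    "pca_cutoff",
    "participation_ratio",
    "parallel_analysis",
]

MatrixLike = Union[np.ndarray, ChannelMatrix]

_EIG_CLIP = -1e-10


def as_samples(data: MatrixLike) -> np.ndarray:
    """Normalise estimator input to a samples x channels float array."""
    if isinstance(data, ChannelMatrix):
        return data.as_samples()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D samples x channels matrix, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input matrix contains NaN/Inf")
    return arr


@dataclass(frozen=True)
class EigenSpectrum:
    """Ordered PCA eigenvalues (variance units) of a channel matrix."""

    eigenvalues: np.ndarray
    total_variance: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < _EIG_CLIP):
            raise ValueError("eigenvalues must be >= -1e-10")
        ev = np.clip(ev, 0.0, None)
        if np.any(np.diff(ev) > 1e-12 * max(ev[0], 1.0)):
            raise ValueError("eigenvalues must be sorted non-increasing")
        object.__setattr__(self, "eigenvalues", ev)
        tot = float(ev.sum())
        if self.total_variance and abs(tot - self.total_variance) > 1e-8 * max(
            abs(self.total_variance), 1.0
        ):
            raise ValueError("total_variance inconsistent with eigenvalue sum")
        object.__setattr__(self, "total_variance", tot)


@dataclass(frozen=True)
class DimensionEstimate:
    """A real-valued dimensionality estimate tagged with its method."""

    value: float
    method: str
    params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Parallel Analysis may legitimately count zero significant
        # eigenvalues on pure noise; every other method must be positive.
        if self.value < 0 or (self.value == 0 and self.method != "PA"):
            raise ValueError(f"dimension estimate must be > 0, got {self.value}")

    @property
    def rounded(self) -> int:
        return int(round(self.value))


def covariance_eigenvalues(samples: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the 1/(M-1) sample covariance."""
    M = samples.shape[0]
    centered = samples - samples.mean(axis=0)
    cov = centered.T @ centered / (M - 1)
    ev = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(ev, 0.0, None)


def eigen_spectrum(data: MatrixLike) -> EigenSpectrum:
    """Eigenvalue spectrum of the mean-centered sample covariance.

    Negative round-off eigenvalues are clipped to zero; order is
    non-increasing.
    """
    samples = as_samples(data)
    if samples.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {samples.shape[0]}")
    ev = covariance_eigenvalues(samples)
    return EigenSpectrum(eigenvalues=ev, total_variance=float(ev.sum()))


def pca_cutoff(spectrum: EigenSpectrum, threshold: float = 0.90) -> DimensionEstimate:
    """Smallest number of leading components whose cumulative variance
    fraction reaches ``threshold`` (0.90 by convention)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ev = spectrum.eigenvalues
    if spectrum.total_variance <= 0:
        raise ValueError("zero total variance: cutoff undefined")
    if threshold == 1.0:
        k = int(np.count_nonzero(ev > 0))
    else:
        frac = np.cumsum(ev) / spectrum.total_variance
        k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    method = "PCA90" if abs(threshold - 0.90) < 1e-12 else "PCA_cutoff"
    return DimensionEstimate(value=float(k), method=method, params={"threshold": threshold})


def participation_ratio(spectrum: EigenSpectrum) -> DimensionEstimate:
    """Participation Ratio ``(sum lambda_i)^2 / sum lambda_i^2``.

    Equals 1 when a single eigenvalue carries all the variance and N when
    all N eigenvalues are equal; scale-invariant in between.
    """
    ev = spectrum.eigenvalues
    denom = float(np.sum(ev**2))
    if spectrum.total_variance <= 0 or denom <= 0:
        raise ValueError("zero total variance: PR undefined")
    pr = float(spectrum.total_variance**2 / denom)
    return DimensionEstimate(value=pr, method="PR", params={})


def parallel_analysis(
    data: MatrixLike,
    n_shuffles: int = 200,
    percentile: float = 95.0,
    seed: int = 0,
) -> DimensionEstimate:
    """Count eigenvalues exceeding a shuffle-based null distribution.

    Each shuffle independently permutes every channel's samples over time,
    destroying cross-channel correlation while preserving marginals; the
    observed eigenvalue at each rank is compared against the given
    percentile (linear interpolation over ``n_shuffles`` draws) of that
    rank's null.  "Exceeds" is strict.
    """
    samples = as_samples(data)
    M, N = samples.shape
    if M < 10:
        raise ValueError(f"parallel analysis needs M >= 10, got {M}")
    if n_shuffles < 10:
        raise ValueError(f"need n_shuffles >= 10, got {n_shuffles}")
    observed = covariance_eigenvalues(samples)
    rng = np.random.default_rng(seed)
    # The null spectra only feed a percentile threshold, so single
    # precision is ample (~1e-7 relative, far below the null spread) and
    # halves the cost of the shuffle loop.
    from scipy.linalg.blas import ssyrk

    work = samples.astype(np.float32)
    null = np.empty((n_shuffles, N))
    for s in range(n_shuffles):
        rng.permuted(work, axis=0, out=work)  # fresh permutation per channel
        centered = work - work.mean(axis=0)
        cov = ssyrk(1.0 / (M - 1), centered, trans=1)  # upper triangle
        null[s] = np.linalg.eigvalsh(cov, UPLO="U")[::-1]
    thresholds = np.percentile(null, percentile, axis=0)
    count = int(np.sum(observed > thresholds))
    return DimensionEstimate(
        value=float(count),
        method="PA",
        params={"n_shuffles": n_shuffles, "percentile": percentile, "seed": seed},
    )
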