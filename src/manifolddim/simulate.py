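"""Synthetic multi-channel neural datasets with known intrinsic dimensionality.

The generator emulates binned firing-rate recordings from a multi-electrode
array: ``d`` non-negative latent signals (uncorrelated across dimensions and,
before smoothing, over time) are temporally smoothed, mixed into ``N``
channels by a random Gaussian matrix, scaled per channel to [0, 1], and
optionally pushed through an exponential point nonlinearity, corrupted with
additive Gaussian noise at a prescribed SNR, and rescaled channel-wise to
mimic heterogeneous firing-rate ranges.  Every stage is deterministic given
the configuration and seed, and all intermediates are retained so the
noise-free embedding can serve as ground truth for denoising metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SimulationConfig",
    "LatentMatrix",
    "ChannelMatrix",
    "SyntheticDataset",
    "sample_latents",
    "gaussian_smooth",
    "linear_mix",
    "scale_unit",
    "exp_activation",
    "exp_activation_inverse",
    "add_noise",
    "rescale_random",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic dataset.

    Parameters
    ----------
    d : int
        Latent (intrinsic) dimensionality, ``1 <= d <= N``.
    M : int
        Number of time samples (bins).
    N : int
        Number of recorded channels; 96 matches a standard Utah array.
    bin_width : float
        Bin duration in seconds (0.05 s = 50 ms spike-count bins).
    smoothing_sd : float
        Gaussian smoothing kernel s.d. in seconds (0.05 s by default, i.e.
        one bin).
    alpha : float or None
        Exponential-activation nonlinearity parameter; ``None`` keeps the
        embedding linear.
    snr_db : float or None
        Per-channel signal-to-noise ratio in dB for additive Gaussian noise;
        ``None`` means noise-free.
    channel_scale_range : (float, float) or None
        If set, each channel is multiplied by an independent draw from
        ``Uniform(lo, hi)`` after (optional) noise, emulating heterogeneous
        firing-rate ranges; requires ``1 <= lo < hi``.
    latent_source : str
        ``"exponential"`` for the built-in surrogate firing-rate
        distribution (exponential, mean 1 spike/bin), or a path to a text
        file with one empirical firing-rate value per line.
    seed : int
        Master seed; all stage RNGs are derived from it.
    """

    d: int
    M: int
    N: int = 96
    bin_width: float = 0.05
    smoothing_sd: float = 0.05
    alpha: Optional[float] = None
    snr_db: Optional[float] = None
    channel_scale_range: Optional[Tuple[float, float]] = None
    latent_source: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.d <= self.N):
            raise ValueError(f"require 1 <= d <= N, got d={self.d}, N={self.N}")
        if self.M < 2:
            raise ValueError(f"require M >= 2, got M={self.M}")
        if self.N < 2:
            raise ValueError(f"require N >= 2, got N={self.N}")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.bin_width <= 0 or self.smoothing_sd < 0:
            raise ValueError("bin_width must be > 0 and smoothing_sd >= 0")
        if self.channel_scale_range is not None:
            lo, hi = self.channel_scale_range
            if not (1 <= lo < hi):
                raise ValueError(
                    f"channel_scale_range must satisfy 1 <= lo < hi, got ({lo}, {hi})"
                )

    @property
    def smoothing_sd_bins(self) -> float:
        return self.smoothing_sd / self.bin_width


@dataclass(frozen=True)
class LatentMatrix:
    """``d x M`` grid of non-negative firing-rate-like latent signals."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"latents must be 2-D (d x M), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("latents contain non-finite entries")
        if np.any(v < 0):
            raise ValueError("latents must be non-negative (firing rates)")
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ChannelMatrix:
    """``N x M`` grid of channel signals (channels x samples internally).

    Estimators consume the samples-x-channels orientation; use
    :meth:`as_samples` at that boundary.
    """

    values: np.ndarray
    channel_order: Tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"channels must be 2-D (N x M), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("channel matrix contains NaN/Inf")
        object.__setattr__(self, "values", v)
        if not self.channel_order:
            object.__setattr__(self, "channel_order", tuple(range(v.shape[0])))
        elif len(self.channel_order) != v.shape[0]:
            raise ValueError("channel_order length must equal channel count")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def as_samples(self) -> np.ndarray:
        """Return an ``M x N`` (samples x channels) copy for estimators."""
        return self.values.T.copy()

    @classmethod
    def from_samples(cls, data: np.ndarray) -> "ChannelMatrix":
        return cls(values=np.asarray(data, dtype=float).T)


@dataclass(frozen=True)
class SyntheticDataset:
    """Ground-truth carrier: config, latents, mixing matrix, clean and
    observed channel matrices, plus per-stage provenance."""

    config: SimulationConfig
    latents: LatentMatrix
    W: np.ndarray
    clean: ChannelMatrix
    observed: ChannelMatrix
    channel_scales: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

_MIN_EMPIRICAL_SAMPLE = 100


def _resolve_source(latent_source: str) -> np.ndarray | str:
    """Return 'exponential' or the loaded empirical sample array."""
    if latent_source == "exponential":
        return "exponential"
    path = Path(latent_source)
    if not path.exists():
        raise ValueError(
            f"unknown latent source {latent_source!r}: not a built-in surrogate "
            "name and not a readable file"
        )
    sample = np.loadtxt(path, dtype=float).ravel()
    if sample.size < _MIN_EMPIRICAL_SAMPLE:
        raise ValueError(
            f"empirical firing-rate file {latent_source!r} has {sample.size} "
            f"values; at least {_MIN_EMPIRICAL_SAMPLE} are required"
        )
    if np.any(sample < 0):
        raise ValueError(
            f"empirical firing-rate file {latent_source!r} contains negative values"
        )
    if not np.all(np.isfinite(sample)):
        raise ValueError(f"empirical firing-rate file {latent_source!r} has NaN/Inf")
    return sample


def sample_latents(
    d: int, M: int, latent_source: str = "exponential", seed: int = 0
) -> LatentMatrix:
    """Draw a ``d x M`` matrix of i.i.d. firing-rate-like values.

    Rows are mutually uncorrelated in expectation by construction (every
    entry is an independent draw), mimicking latent signals sampled
    independently across dimensions and time bins.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    rng = np.random.default_rng(seed)
    source = _resolve_source(latent_source)
    if isinstance(source, str):  # built-in exponential surrogate, mean 1 spike/bin
        values = rng.exponential(scale=1.0, size=(d, M))
    else:
        values = rng.choice(source, size=(d, M), replace=True)
    return LatentMatrix(values=values)


def gaussian_smooth(latents: LatentMatrix, sd_bins: float) -> LatentMatrix:
    """Convolve each latent row with a unit-area Gaussian kernel.

    The kernel is a discrete Gaussian truncated at +-4 s.d., renormalised to
    unit sum, with reflective boundary handling (avoids edge attenuation).
    ``sd_bins = 0`` is the identity.
    """
    if sd_bins < 0:
        raise ValueError(f"sd_bins must be >= 0, got {sd_bins}")
    if sd_bins == 0:
        return latents
    smoothed = gaussian_filter1d(
        latents.values, sigma=sd_bins, axis=1, mode="reflect", truncate=4.0
    )
    # positive kernel on non-negative input: clip away -0.0 rounding only
    return LatentMatrix(values=np.clip(smoothed, 0.0, None))


def linear_mix(
    latents: LatentMatrix, N: int, seed: int = 0
) -> Tuple[ChannelMatrix, np.ndarray]:
    """Mix ``d`` latents into ``N`` channels with an i.i.d. standard-normal
    ``N x d`` matrix ``W``; returns ``(W @ latents, W)``."""
    if N < latents.d:
        raise ValueError(
            f"N ({N}) must be >= d ({latents.d}): undercomplete mixing would "
            "change the ground-truth dimensionality"
        )
    rng = np.random.default_rng(seed)
    W = rng.standard_normal(size=(N, latents.d))
    return ChannelMatrix(values=W @ latents.values), W


def scale_unit(channels: ChannelMatrix) -> ChannelMatrix:
    """Per-channel affine min-max map onto [0, 1].

    Required by the exponential activation, whose domain is [0, 1]; every
    channel attains both bounds exactly.
    """
    v = channels.values
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    bad = np.nonzero(span.ravel() == 0)[0]
    if bad.size:
        raise ValueError(
            f"cannot unit-scale constant channel(s) {bad.tolist()}: zero range"
        )
    return ChannelMatrix(values=(v - lo) / span, channel_order=channels.channel_order)


def exp_activation(channels: ChannelMatrix, alpha: float) -> ChannelMatrix:
    """Elementwise exponential activation ``f(x) = (e^{ax} - 1)/(e^a - 1)``.

    A strictly monotone bijection of [0, 1] for every ``alpha > 0``; the
    ``alpha -> 0`` limit is the identity.  Implemented with ``expm1`` so tiny
    ``alpha`` values remain numerically exact.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    v = channels.values
    if v.min() < 0 or v.max() > 1:
        raise ValueError(
            "exponential activation requires entries in [0, 1]; "
            f"got range [{v.min():.4g}, {v.max():.4g}]"
        )
    out = np.expm1(alpha * v) / np.expm1(alpha)
    return ChannelMatrix(
        values=np.clip(out, 0.0, 1.0), channel_order=channels.channel_order
    )


def exp_activation_inverse(channels: ChannelMatrix, alpha: float) -> ChannelMatrix:
    """Inverse of :func:`exp_activation`: ``x = log1p(y * expm1(a)) / a``."""
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    v = channels.values
    out = np.log1p(v * np.expm1(alpha)) / alpha
    return ChannelMatrix(values=out, channel_order=channels.channel_order)


def add_noise(channels: ChannelMatrix, snr_db: float, seed: int = 0) -> ChannelMatrix:
    """Add zero-mean Gaussian noise per channel at a prescribed SNR.

    Noise variance for channel ``i`` is ``var(x_i) / 10^(snr_db/10)``;
    independent across channels and samples.  20 dB means 1% noise power,
    7 dB about 20%.  ``snr_db = inf`` disables noise.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return channels
    if not np.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite (or +inf sentinel), got {snr_db}")
    v = channels.values
    sig_var = v.var(axis=1, ddof=0, keepdims=True)
    if np.any(sig_var == 0):
        raise ValueError("cannot define SNR for constant channel(s)")
    noise_sd = np.sqrt(sig_var / 10 ** (snr_db / 10))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(size=v.shape) * noise_sd
    return ChannelMatrix(values=v + noise, channel_order=channels.channel_order)


def rescale_random(
    channels: ChannelMatrix, lo: float, hi: float, seed: int = 0
) -> Tuple[ChannelMatrix, np.ndarray]:
    """Multiply each channel by an independent ``Uniform(lo, hi)`` draw.

    Emulates the up-to-10-fold heterogeneity of firing-rate variance across
    real channels.  Returns the rescaled matrix and the scale vector.
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    rng = np.random.default_rng(seed)
    scales = rng.uniform(lo, hi, size=channels.N)
    out = ChannelMatrix(
        values=channels.values * scales[:, None], channel_order=channels.channel_order
    )
    return out, scales


# ---------------------------------------------------------------------------
# Full composition
# ---------------------------------------------------------------------------

def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across added stages)."""
    import zlib

    return int(
        np.random.SeedSequence(
            [int(master) % (2**31), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from a :class:`SimulationConfig`.

    Stages: sample latents -> Gaussian smoothing -> linear mixing ->
    per-channel [0,1] scaling -> optional exponential activation ->
    optional additive noise -> optional random channel rescaling.
    ``clean`` is the post-embedding, pre-noise matrix; ``observed`` is the
    final product.  Byte-stable for a fixed (config, seed).
    """
    stage = "sample_latents"
    try:
        latents = sample_latents(
            config.d, config.M, config.latent_source, _stage_seed(config.seed, stage)
        )
        stage = "gaussian_smooth"
        smoothed = gaussian_smooth(latents, config.smoothing_sd_bins)
        stage = "linear_mix"
        mixed, W = linear_mix(smoothed, config.N, _stage_seed(config.seed, stage))
        stage = "scale_unit"
        clean = scale_unit(mixed)
        if config.alpha is not None:
            stage = "exp_activation"
            clean = exp_activation(clean, config.alpha)
        observed = clean
        if config.snr_db is not None:
            stage = "add_noise"
            observed = add_noise(
                observed, config.snr_db, _stage_seed(config.seed, stage)
            )
        channel_scales = None
        if config.channel_scale_range is not None:
            stage = "rescale_random"
            lo, hi = config.channel_scale_range
            observed, channel_scales = rescale_random(
                observed, lo, hi, _stage_seed(config.seed, stage)
            )
    except ValueError as err:
        raise ValueError(f"simulation stage {stage!r} failed: {err}") from err
    return SyntheticDataset(
        config=config,
        latents=smoothed,
        W=W,
        clean=clean,
        observed=observed,
        channel_scales=channel_scales,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed (replication helper)."""
    return replace(config, seed=seed)
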