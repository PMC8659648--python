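"""Denoising of multi-channel recordings prior to dimensionality estimation.

Channel-independent noise inflates every dimensionality estimate, so the
data are first projected through a bottleneck of width ``D`` (an upper-bound
dimensionality, typically from Parallel Analysis) and reconstructed.  Two
routes are provided:

* **PCA denoising** — reconstruct from the ``D`` leading principal
  components; optimal if the manifold is linear, since low-variance
  components carry mostly noise.
* **Joint Autoencoder (JAE)** — the channels are randomly split into two
  halves, each compressed to a ``D``-dimensional code and reconstructed by
  its own ReLU autoencoder; the training cost

      C = MSE(X1, X1_hat) + MSE(X2, X2_hat) + MSE(Z1, Z2)

  additionally penalises disagreement between the two codes.  Signal shared
  across channels survives the bottleneck agreement term while independent
  noise, which differs between the halves, does not.  The network (ReLU
  layers throughout, Adam optimiser, input-layer dropout) is implemented
  directly in numpy — the model is small enough that no GPU framework is
  needed.

Reconstruction quality is scored with multivariate Variance Accounted For
(VAF); comparing the PCA and JAE reconstruction VAFs against the *noisy*
input doubles as a practical nonlinearity detector (see the pipeline
module).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .linear import covariance_eigenvalues
from .simulate import ChannelMatrix

__all__ = [
    "JAEHyperparams",
    "DenoiseResult",
    "JAEModel",
    "vaf",
    "pca_denoise",
    "train_jae",
    "jae_denoise",
    "jae_cost",
]


# ---------------------------------------------------------------------------
# VAF
# ---------------------------------------------------------------------------

def vaf(reference: ChannelMatrix, estimate: ChannelMatrix) -> float:
    """Pooled multivariate Variance Accounted For.

    ``1 - SS_res / SS_tot`` where ``SS_tot`` sums squared deviations of the
    reference from its per-channel means over all entries.  The reference
    comes first; VAF is not symmetric.
    """
    if reference.values.shape != estimate.values.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.values.shape} vs "
            f"estimate {estimate.values.shape}"
        )
    ref = reference.values
    ss_tot = float(np.sum((ref - ref.mean(axis=1, keepdims=True)) ** 2))
    if ss_tot == 0:
        raise ValueError("reference has zero variance: VAF undefined")
    ss_res = float(np.sum((ref - estimate.values) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Result / hyperparameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiseResult:
    denoised: ChannelMatrix
    method: str  # "PCA" | "JAE"
    D: int
    vaf_vs_input: float
    vaf_vs_reference: Optional[float] = None
    training_log: Optional[List[float]] = None
    flags: Dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class JAEHyperparams:
    """Training knobs for the Joint Autoencoder.

    Defaults: one hidden ReLU layer of 64 units per encoder/decoder half,
    Adam at learning rate 1e-3, dropout p=0.05 on the input layer only,
    up to 2000 epochs with early stopping after 50 epochs without
    improvement of the epoch training loss.
    """

    bottleneck_D: int
    hidden_width: int = 64
    learning_rate: float = 1e-3
    dropout_p: float = 0.05
    max_epochs: int = 2000
    batch_size: int = 64
    patience: int = 50
    min_delta: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottleneck_D < 1:
            raise ValueError("bottleneck_D must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# PCA denoising
# ---------------------------------------------------------------------------

def pca_denoise(
    data: ChannelMatrix, D: int, reference: Optional[ChannelMatrix] = None
) -> DenoiseResult:
    """Reconstruct the data from its ``D`` leading principal components."""
    if not 1 <= D <= data.N:
        raise ValueError(f"require 1 <= D <= N={data.N}, got D={D}")
    X = data.as_samples()  # M x N
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / (X.shape[0] - 1)
    ev, vec = np.linalg.eigh(cov)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    V = vec[:, :D]
    recon = centered @ V @ V.T + mean
    denoised = ChannelMatrix(values=recon.T, channel_order=data.channel_order)
    rank = int(np.sum(ev > max(ev[0], 0) * 1e-12))
    flags = {"D_exceeds_rank": D > rank}
    result_vaf = vaf(data, denoised)
    ref_vaf = vaf(reference, denoised) if reference is not None else None
    return DenoiseResult(
        denoised=denoised,
        method="PCA",
        D=D,
        vaf_vs_input=result_vaf,
        vaf_vs_reference=ref_vaf,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Joint Autoencoder
# ---------------------------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _HalfAutoencoder:
    """One ReLU autoencoder half: in -> hidden -> D -> hidden -> in."""

    def __init__(self, n_in: int, hidden: int, D: int, rng: np.random.Generator):
        def he(shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / shape[0])

        # params: list of (W, b) for the 4 layers
        self.params = [
            [he((n_in, hidden)), np.zeros(hidden)],
            [he((hidden, D)), np.zeros(D)],
            [he((D, hidden)), np.zeros(hidden)],
            [he((hidden, n_in)), np.zeros(n_in)],
        ]

    def forward(self, x: np.ndarray):
        """Returns (activations per layer, code Z, reconstruction)."""
        acts = [x]
        h = x
        for W, b in self.params:
            h = _relu(h @ W + b)
            acts.append(h)
        return acts  # acts[2] is Z, acts[4] is reconstruction

    def backward(self, acts, d_out: np.ndarray, d_code: np.ndarray):
        """Backprop given gradients w.r.t. reconstruction and code.

        Returns per-parameter gradients in layer order.
        """
        grads = [[None, None] for _ in self.params]
        delta = d_out * (acts[4] > 0)
        for layer in (3, 2):
            W, _ = self.params[layer]
            grads[layer][0] = acts[layer].T @ delta
            grads[layer][1] = delta.sum(axis=0)
            delta = delta @ W.T
            if layer == 2:
                delta = delta + d_code  # inject bottleneck-agreement gradient
            delta = delta * (acts[layer] > 0)
        for layer in (1, 0):
            W, _ = self.params[layer]
            grads[layer][0] = acts[layer].T @ delta
            grads[layer][1] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ W.T) * (acts[layer] > 0)
        return grads


@dataclass
class JAEModel:
    """Trained Joint Autoencoder: two half-networks plus the channel
    partition they were trained on."""

    net1: _HalfAutoencoder
    net2: _HalfAutoencoder
    partition1: np.ndarray  # channel indices of half 1
    partition2: np.ndarray
    hyper: JAEHyperparams
    loss_trace: List[float]
    final_loss: float

    @property
    def n_channels(self) -> int:
        return self.partition1.size + self.partition2.size


def jae_cost(
    X1: np.ndarray, X1_hat: np.ndarray,
    X2: np.ndarray, X2_hat: np.ndarray,
    Z1: np.ndarray, Z2: np.ndarray,
) -> float:
    """The Joint Autoencoder objective
    ``MSE(X1, X1_hat) + MSE(X2, X2_hat) + MSE(Z1, Z2)`` (equal weights)."""
    return float(
        np.mean((X1 - X1_hat) ** 2)
        + np.mean((X2 - X2_hat) ** 2)
        + np.mean((Z1 - Z2) ** 2)
    )


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def train_jae(data: ChannelMatrix, hyper: JAEHyperparams) -> JAEModel:
    """Train the Joint Autoencoder on a non-negative channel matrix.

    Channels are randomly partitioned into two near-equal halves (sizes
    differ by at most one; the extra channel goes to half 1).  Each half is
    mapped through a ``D``-wide ReLU bottleneck; both halves see the same
    samples, so the bottleneck-agreement term of the cost is the mean
    squared elementwise difference of the two codes per sample.  Training
    uses minibatch Adam with inverted dropout on the inputs and early
    stopping on the epoch training loss.
    """
    # Inputs are rate-like ([0,1]-scaled signals) but additive noise pushes
    # entries below zero; those excursions are legitimate training targets.
    # The ReLU output layer keeps every reconstruction non-negative, so the
    # denoised signals remain rate-like regardless.
    N = data.N
    D = hyper.bottleneck_D
    if N < 2 * D:
        raise ValueError(
            f"bottleneck D={D} wider than a partition: need N >= 2D, got N={N}"
        )
    rng = np.random.default_rng(hyper.seed)
    perm = rng.permutation(N)
    n1 = (N + 1) // 2
    part1, part2 = np.sort(perm[:n1]), np.sort(perm[n1:])

    X = data.as_samples()  # M x N
    X1_full, X2_full = X[:, part1], X[:, part2]
    M = X.shape[0]

    net1 = _HalfAutoencoder(part1.size, hyper.hidden_width, D, rng)
    net2 = _HalfAutoencoder(part2.size, hyper.hidden_width, D, rng)
    all_params = [p for net in (net1, net2) for layer in net.params for p in layer]
    opt = _Adam([p.shape for p in all_params], hyper.learning_rate)

    best = np.inf
    stall = 0
    trace: List[float] = []
    keep_p = 1.0 - hyper.dropout_p
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(M)
        epoch_loss = 0.0
        for start in range(0, M, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            x1, x2 = X1_full[idx], X2_full[idx]
            if hyper.dropout_p > 0:
                in1 = x1 * (rng.random(x1.shape) < keep_p) / keep_p
                in2 = x2 * (rng.random(x2.shape) < keep_p) / keep_p
            else:
                in1, in2 = x1, x2
            acts1 = net1.forward(in1)
            acts2 = net2.forward(in2)
            z1, z2 = acts1[2], acts2[2]
            xh1, xh2 = acts1[4], acts2[4]
            B = idx.size
            loss = jae_cost(x1, xh1, x2, xh2, z1, z2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite JAE training loss at epoch {epoch}"
                )
            epoch_loss += loss * B
            # gradients of the three mean-squared terms
            d_x1 = 2.0 * (xh1 - x1) / (B * x1.shape[1])
            d_x2 = 2.0 * (xh2 - x2) / (B * x2.shape[1])
            d_z = 2.0 * (z1 - z2) / (B * D)
            g1 = net1.backward(acts1, d_x1, d_z)
            g2 = net2.backward(acts2, d_x2, -d_z)
            grads = [g for net_g in (g1, g2) for layer in net_g for g in layer]
            opt.step(all_params, grads)
        epoch_loss /= M
        trace.append(epoch_loss)
        if best - epoch_loss > hyper.min_delta:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= hyper.patience:
                break
    return JAEModel(
        net1=net1,
        net2=net2,
        partition1=part1,
        partition2=part2,
        hyper=hyper,
        loss_trace=trace,
        final_loss=trace[-1],
    )


def jae_denoise(
    model: JAEModel,
    data: ChannelMatrix,
    reference: Optional[ChannelMatrix] = None,
) -> DenoiseResult:
    """Pass data through a trained Joint Autoencoder (dropout disabled) and
    reassemble the two reconstructed halves in original channel order."""
    if data.N != model.n_channels:
        raise ValueError(
            f"channel mismatch: model trained on {model.n_channels} channels, "
            f"data has {data.N}"
        )
    X = data.as_samples()
    xh1 = model.net1.forward(X[:, model.partition1])[4]
    xh2 = model.net2.forward(X[:, model.partition2])[4]
    recon = np.empty_like(X)
    recon[:, model.partition1] = xh1
    recon[:, model.partition2] = xh2
    denoised = ChannelMatrix(values=recon.T, channel_order=data.channel_order)
    ref_vaf = vaf(reference, denoised) if reference is not None else None
    return DenoiseResult(
        denoised=denoised,
        method="JAE",
        D=model.hyper.bottleneck_D,
        vaf_vs_input=vaf(data, denoised),
        vaf_vs_reference=ref_vaf,
        training_log=model.loss_trace,
    )
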