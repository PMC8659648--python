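# Methods

This note documents the models, algorithms, defaults and design choices
behind `manifolddim`, in the order a dataset flows through the package.

## The problem

Multi-electrode recordings of a neural population are high-dimensional
(one channel per electrode, here N = 96 by default, matching a Utah
array), but the population's coordinated firing is believed to be confined
to a low-dimensional manifold. The *intrinsic dimensionality* d of that
manifold — the number of latent degrees of freedom needed to describe the
activity without significant information loss — is the quantity every
component of this package either fabricates (the simulator), estimates
(the estimators), or protects from noise (the denoisers and the pipeline).

Two features of real recordings make the estimation hard: the map from
latent signals to channels may be nonlinear, and the channels carry noise
that is independent across electrodes. The package therefore benchmarks
estimators on synthetic data where d, the embedding nonlinearity, and the
noise level are all controlled.

## Synthetic data generator

A dataset is produced by the following pipeline (all stages deterministic
given the configuration and a master seed; per-stage seeds are derived by
hashing the stage label so adding a stage never perturbs another):

1. **Latents** — a d x M matrix of i.i.d. draws from a firing-rate-like
   distribution. The default surrogate is exponential with mean 1
   spike/bin: non-negative and right-skewed like binned cortical firing
   rates. A file of empirical rates (one value per line, >= 100 values)
   can replace the surrogate, in which case latents are drawn from it with
   replacement. Rows are uncorrelated by construction.
2. **Temporal smoothing** — each latent row is convolved with a unit-area
   discrete Gaussian (default s.d. 50 ms = 1 bin at the 50 ms bin width),
   truncated at +-4 s.d. and renormalised, with reflective boundaries to
   avoid edge attenuation. Smoothing white noise with a unit-s.d. kernel
   leaves lag-1 autocorrelation exp(-1/4) ~ 0.78, which the tests verify.
3. **Mixing** — multiplication by an N x d matrix W of i.i.d. standard
   normal entries. Undercomplete mixing (N < d) is rejected because it
   would silently change the ground truth.
4. **Unit scaling** — each channel is min-max mapped onto [0, 1]. This is
   required because the activation in step 5 is only defined on [0, 1].
   (An alternative reading of the procedure — dividing each channel by its
   maximum only — leaves signed values whose negative half the activation
   collapses toward zero; it produces near-constant channels for which a
   per-channel SNR is undefined and degrades the nonlinear estimators on
   noise-free data, so min-max was adopted.)
5. **Nonlinearity (optional)** — elementwise
   `f(x) = (exp(alpha*x) - 1) / (exp(alpha) - 1)`, a strictly monotone
   bijection of [0, 1] for every alpha > 0 whose alpha -> 0 limit is the
   identity. The exponential form is the canonical inverse-link for
   Poisson-like count data. alpha = 16 is the "highly nonlinear" reference
   condition. Implemented with `expm1` so small alpha stays exact.
6. **Noise (optional)** — zero-mean Gaussian noise added per channel with
   variance `var(channel) / 10^(snr_db/10)`, independent across channels
   and samples. 20 dB means 1% noise power, 7 dB about 20%. SNR is defined
   per channel so the dB level stays meaningful after step 7.
7. **Random rescaling (optional)** — each channel multiplied by an
   independent Uniform(lo, hi) draw (default 1..10), emulating the up to
   10-fold spread of firing-rate variance across real electrodes.

The matrix after step 5 (`clean`) is the noise-free ground truth used as
the reference for denoising VAF. For a linear embedding, its *covariance*
has exactly d non-negligible eigenvalues; the raw matrix rank is
generically d + 1 because the [0,1] scaling adds a channel-specific
offset.

Default M = 6000 samples for single-condition experiments (five minutes of
50 ms bins) — inside the regime where all estimators have enough data —
with M swept over 100..12000 in the data-amount benchmark.

**What the generator does not emulate:** spiking discreteness (latents are
continuous), temporal dynamics or trial structure (samples are exchangeable
population states by design), non-Gaussian or correlated noise, and
electrode-level artifacts. Passing benchmarks therefore demonstrates
estimator behavior under controlled geometry and noise, not robustness to
every property of experimental recordings. The marginal latent
distribution is a surrogate; magnitudes that depend on fine local geometry
(e.g. exactly how much a given SNR inflates a neighbor-based estimate)
shift noticeably when the marginal changes, while breakpoints and
orderings are stable.

## Linear estimators

All operate on the eigenvalues {lambda_i} of the 1/(M-1) sample covariance
of mean-centered data (clipped at zero, sorted descending).

- **PCA with variance cutoff** — the smallest k whose leading k
  eigenvalues reach 90% cumulative variance.
- **Participation Ratio** — `PR = (sum lambda_i)^2 / sum lambda_i^2`;
  1 when one eigenvalue carries everything, N when all N are equal;
  scale-invariant and reported as a real number.
- **Parallel Analysis** — each of 200 shuffles permutes every channel's
  samples independently over time (destroying cross-channel correlation,
  preserving marginals); the observed eigenvalue at each rank is compared
  with the 95th percentile (linear interpolation) of that rank's null;
  the estimate is the number of strict exceedances. No correction across
  ranks is applied, matching the method's standard description; with ~5%
  per-rank false positives the estimate on pure noise stays at 0-2.

## Nonlinear estimators

All are translation-, rotation- and scale-invariant, use Euclidean
distances, and remove exact duplicate points first (zero distances break
the log statistics; removal counts are logged, > 1% triggers a warning).

- **Correlation Dimension** — slope of log C(r) vs log r, where C(r) is
  the fraction of point pairs closer than r, evaluated on 32 log-spaced
  radii between the 1st and 99th percentile of pairwise distances and
  fitted over the 2nd-25th percentile band. The band sits below the
  saturation shoulder of the curve; fitting higher bands biases the slope
  low on compact manifolds (verified on circles, squares and cubes of
  known dimension).
- **Levina-Bickel MLE** — per point and neighbor count k, the inverse mean
  log-ratio of the k-th to the j-th neighbor distance (j < k); averaged
  over points, then over k in [k1, k2] = [10, 20] (the original authors'
  recommendation; the harmonic-style MacKay-Ghahramani aggregation is
  available behind a flag).
- **Two Nearest Neighbors** — the ratio mu = r2/r1 of second- to
  first-neighbor distances satisfies F(mu) = 1 - mu^(-d) on a locally
  uniform d-manifold; d is the origin-constrained slope of
  -ln(1 - F) on ln mu over the empirical CDF, after discarding the top 10%
  of ratios (heavy tail; the F = 1 point is always discarded).
- **Fisher Separability Analysis** — data are centered, projected onto
  principal components individually explaining >= 1/(2N) of variance,
  whitened, and normalised to the unit sphere; a point x is separable from
  y at threshold alpha_sep = 0.8 iff <x, y> <= alpha_sep. The mean
  pairwise inseparability probability p is matched to the closed form
  `p(a, d) = (1 - a^2)^((d-1)/2) / (a * sqrt(2*pi*d))` by Brent root
  finding on log p. The (d-1)/2 exponent is the spherical-cap form
  consistent with the sphere projection: it gives p = 1/2 exactly at
  d = 1 and matches brute-force pair counts on uniform spheres. The
  original method's uniform-ball exponent (d+1)/2 is available via
  `calibration="ball"`; inverting it against sphere-projected data biases
  the estimate low, which is the documented mild underestimation of that
  estimator. If p = 0 (every point separable) the relation cannot be
  inverted and the projection rank is returned with a saturation flag.

## Denoising

Channel-independent noise pushes every estimator toward N, so estimation
should follow denoising. Both denoisers compress to a bottleneck D — the
Parallel-Analysis upper bound, floored at 1 — and reconstruct.

- **PCA denoising** reconstructs from the D leading components
  (deterministic, idempotent, exact when D >= rank).
- **Joint Autoencoder** randomly splits the channels into two near-equal
  halves (odd channel to half 1) and trains one ReLU autoencoder per half
  (input -> hidden(64) -> D -> hidden(64) -> input), minimising
  `MSE(X1, X1_hat) + MSE(X2, X2_hat) + MSE(Z1, Z2)` with equal weights.
  The code-agreement term is the keystone: shared signal can be encoded
  consistently by both halves, independent noise cannot. Both halves see
  the same samples, so the term is the elementwise mean squared difference
  of the two D-wide codes; no unit alignment beyond the loss itself is
  needed. Training uses minibatch Adam (lr 1e-3, batch 64), inverted
  dropout p = 0.05 on the input layer only, and early stopping when the
  epoch training loss fails to improve by more than 1e-7 for 50 epochs
  (no validation split; max 2000 epochs). All layers are ReLU, so
  reconstructions are non-negative (rate-like) by construction. Inputs may
  contain negative noise excursions; they are legitimate targets for the
  reconstruction terms. The network is small enough that the trainer is
  plain numpy (hand-written backprop and Adam); a fixed seed makes
  training bit-reproducible.
- **VAF** — reconstruction quality is `1 - SS_res / SS_tot`, pooled over
  all entries, with SS_tot measured around per-channel means of the
  reference (first argument; VAF is not symmetric).

## Recommended pipeline

1. Upper bound D from Parallel Analysis (floor 1, with a warning).
2. Denoise with PCA and with the JAE at bottleneck D.
3. Compare reconstruction VAFs *against the noisy input* — the only
   reference available for real data. JAE exceeding PCA by more than a
   margin (default 0.02, guarding against trainer noise) flags a nonlinear
   manifold; otherwise the manifold is treated as linear.
4. On the chosen branch's denoised signals: Parallel Analysis, LBMLE and
   TNN are all computed; the final estimate is PA on the linear branch and
   LBMLE on the nonlinear branch (LBMLE needs fewer samples than TNN,
   which is reported alongside as a cross-check).

## Benchmark harness and statistics

`run_sweep` replays the study conditions as presets (noise-free, unequal
variance, d-sweep, alpha-sweep, data-amount, noise, denoising) over grids
that include every breakpoint named in the results: d in {3,...,40}, alpha
in {1,...,32}, SNR in {20,10,7} dB, M log-spaced 100..12000, N in
{5,...,96}. Replications default to n = 10 (n = 3 for the d-sweep); each
replication re-runs the full generator with a child seed, so a sweep is
bit-reproducible from its master seed. Per-cell failures are recorded with
a reason, never aborting the sweep.

Uncertainty is summarised by a percentile bootstrap of the mean (10,000
resamples, alpha = 0.05) with Bonferroni correction across the cells of a
summary. An estimator is flagged *accurate* when the corrected CI contains
the true d. Because synthetic replications can agree to within ~0.01-0.05
dimensions, the CI can collapse to near-zero width and flag a 2% bias as
significant; the summary therefore also reports the robust criterion
|mean - d| < 0.5 ("recovers the dimensionality to within half a
dimension"), and breakpoint determinations use "CI contains d OR
|mean - d| < 0.5". Measured this way the package reproduces the headline
breakpoints: PA needs >= 20 channels, stays accurate only for d <= 20 and
up to alpha = 8; LBMLE becomes accurate from M = 600 samples.

## Problem sizes

Acceptance computations (`scripts/acceptance.py`) run the stated study
conditions (d = 6, N = 96, M = 6000, alpha = 16 where nonlinear) with
n = 10 replications for the noise-free and 20 dB conditions, n = 5 for
the channel-count, sample-count and alpha sweeps, n = 3 for the d-sweep (the
study's own choice there) and for the Joint-Autoencoder condition, where
CPU training dominates runtime. The test suite uses further-reduced
replication counts and, for unit tests, smaller M; condition parameters
are never reduced.

## Known limitations

- Magnitudes that hinge on the latent marginal (e.g. the exact percent
  overestimation a given SNR induces in LBMLE/TNN) vary by tens of percent
  across plausible surrogate distributions; orderings and breakpoints are
  the robust outputs.
- The JAE architecture (one hidden layer of 64 units per half) is the
  smallest consistent with a compressive/expansive design; no architecture
  search is performed. Early stopping monitors training loss only.
- Correlation Dimension needs on the order of 10^(d/2) samples and runs
  low for d >= 6 at feasible M; it is included for completeness, not used
  by the pipeline.
- No temporal modelling: estimators treat samples as exchangeable states.
  Dynamics-aware denoisers are out of scope.
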