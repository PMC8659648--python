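"""Monte Carlo benchmark harness: condition sweeps, bootstrap intervals,
and the accuracy criterion used to score estimators against ground truth.

Each preset reproduces one of the study's simulation experiments at a
configurable scale: noise-free recovery, unequal channel variances, a
true-dimensionality sweep, a nonlinearity (alpha) sweep, a data-amount
sweep over samples and channels, a noise (SNR) sweep, and a denoising
comparison.  Per-condition replications differ only by derived child seeds,
so a sweep re-run with the same master seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .denoise import JAEHyperparams, jae_denoise, pca_denoise, train_jae, vaf
from .io import child_seed
from .linear import eigen_spectrum, parallel_analysis, participation_ratio, pca_cutoff
from .nonlinear import (
    correlation_dimension,
    fisher_separability_dimension,
    lbmle,
    two_nn,
)
from .pipeline import upper_bound_dimension
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "BootstrapInterval",
    "SweepResult",
    "bootstrap_ci",
    "accuracy_flag",
    "run_sweep",
    "PRESETS",
    "DEFAULT_GRIDS",
]


# ---------------------------------------------------------------------------
# Bootstrap statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapInterval:
    mean: float
    lo: float
    hi: float
    alpha: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError("bootstrap interval must bracket the mean")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def bootstrap_ci(
    samples: Sequence[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapInterval:
    """Percentile bootstrap confidence interval for the mean."""
    arr = np.asarray(list(samples), dtype=float)
    if arr.size < 2:
        raise ValueError(f"bootstrap needs >= 2 samples, got {arr.size}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    mean = float(arr.mean())
    return BootstrapInterval(
        mean=mean, lo=min(float(lo), mean), hi=max(float(hi), mean),
        alpha=alpha, n_boot=n_boot,
    )


def accuracy_flag(
    estimates: Sequence[float],
    true_d: float,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    n_boot: int = 10_000,
    seed: int = 0,
) -> bool:
    """True iff the Bonferroni-adjusted bootstrap CI of the mean contains
    the true dimensionality (no significant difference)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    ci = bootstrap_ci(
        estimates, n_boot=n_boot, alpha=alpha / n_comparisons, seed=seed
    )
    return ci.contains(float(true_d))


# ---------------------------------------------------------------------------
# Estimator registry
# ---------------------------------------------------------------------------

def _est_pca90(samples: np.ndarray, seed: int) -> float:
    return pca_cutoff(eigen_spectrum(samples), 0.90).value


def _est_pr(samples: np.ndarray, seed: int) -> float:
    return participation_ratio(eigen_spectrum(samples)).value


def _est_pa(samples: np.ndarray, seed: int) -> float:
    return parallel_analysis(samples, seed=seed).value


def _est_cd(samples: np.ndarray, seed: int) -> float:
    return correlation_dimension(samples).value


def _est_lbmle(samples: np.ndarray, seed: int) -> float:
    return lbmle(samples).value


def _est_tnn(samples: np.ndarray, seed: int) -> float:
    return two_nn(samples).value


def _est_fsa(samples: np.ndarray, seed: int) -> float:
    return fisher_separability_dimension(samples).value


ESTIMATORS: Dict[str, Callable[[np.ndarray, int], float]] = {
    "PCA90": _est_pca90,
    "PR": _est_pr,
    "PA": _est_pa,
    "CD": _est_cd,
    "LBMLE": _est_lbmle,
    "TNN": _est_tnn,
    "FSA": _est_fsa,
}

ALL_METHODS = ["PCA90", "PR", "PA", "CD", "LBMLE", "TNN", "FSA"]
CORE_METHODS = ["PA", "LBMLE", "TNN"]

# Condition grids; every breakpoint named in the study's results is included.
DEFAULT_GRIDS: Dict[str, Any] = {
    "d_values": [3, 4, 6, 8, 10, 13, 16, 20, 25, 30, 40],
    "alpha_values": [1, 2, 4, 8, 16, 32],
    "snr_values": [20, 10, 7],
    "M_values": [100, 200, 400, 600, 1200, 2500, 5000, 12000],
    "N_values": [5, 10, 15, 20, 30, 50, 96],
    "d": 6,
    "M": 6000,
    "N": 96,
    "alpha": 16.0,
}


# ---------------------------------------------------------------------------
# Sweep result container
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    preset: str
    table: pd.DataFrame  # long format: condition fields, replication, method, estimate
    n_replications: int
    master_seed: int
    seeds: List[int] = field(default_factory=list)

    def summarize(
        self,
        alpha: float = 0.05,
        n_boot: int = 10_000,
        bonferroni: bool = True,
        rounded_tolerance: float = 0.5,
    ) -> pd.DataFrame:
        """Per condition x method: mean, sd, bootstrap CI, accuracy flags.

        ``accurate`` follows the CI criterion (Bonferroni-corrected across
        all condition x method cells when ``bonferroni``); ``accurate_rounded``
        is the secondary |mean - d| < tolerance criterion.
        """
        cond_cols = ["d", "alpha", "snr_db", "N", "M", "rescaled"]
        ok = self.table[~self.table["failed"]]
        groups = list(ok.groupby(cond_cols + ["method"], dropna=False))
        n_comp = len(groups) if bonferroni else 1
        rows = []
        for key, grp in groups:
            est = grp["estimate"].to_numpy(dtype=float)
            rec: Dict[str, Any] = dict(zip(cond_cols + ["method"], key))
            rec["n"] = est.size
            rec["mean"] = est.mean()
            rec["sd"] = est.std(ddof=1) if est.size > 1 else 0.0
            if est.size >= 2:
                ci = bootstrap_ci(
                    est, n_boot=n_boot, alpha=alpha / n_comp,
                    seed=child_seed(self.master_seed, "summary_ci"),
                )
                rec["ci_lo"], rec["ci_hi"] = ci.lo, ci.hi
                rec["accurate"] = ci.contains(float(rec["d"]))
            else:
                rec["ci_lo"] = rec["ci_hi"] = est.mean()
                rec["accurate"] = abs(est.mean() - rec["d"]) < rounded_tolerance
            rec["accurate_rounded"] = abs(rec["mean"] - rec["d"]) < rounded_tolerance
            rows.append(rec)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preset grids
# ---------------------------------------------------------------------------

def _merge_scale(scale: Optional[Dict[str, Any]]) -> Dict[str, Any]:
    grids = dict(DEFAULT_GRIDS)
    if scale:
        unknown = set(scale) - set(grids) - {"n", "methods", "jae_max_epochs"}
        if unknown:
            raise ValueError(f"unknown scale keys: {sorted(unknown)}")
        grids.update(scale)
    return grids


def _conditions(preset: str, g: Dict[str, Any]) -> List[Dict[str, Any]]:
    base = dict(d=g["d"], alpha=None, snr_db=None, N=g["N"], M=g["M"], rescaled=False)
    if preset == "noise_free":
        return [dict(base), dict(base, alpha=g["alpha"])]
    if preset == "unequal_variance":
        return [dict(base, rescaled=True), dict(base, alpha=g["alpha"], rescaled=True)]
    if preset == "d_sweep":
        conds = []
        for d in g["d_values"]:
            conds.append(dict(base, d=d))
            conds.append(dict(base, d=d, alpha=g["alpha"]))
        return conds
    if preset == "alpha_sweep":
        return [dict(base, alpha=a) for a in g["alpha_values"]]
    if preset == "data_amount":
        conds = []
        for alpha in (None, g["alpha"]):
            for N in g["N_values"]:
                for M in g["M_values"]:
                    conds.append(dict(base, alpha=alpha, N=N, M=M))
        return conds
    if preset == "noise":
        conds = []
        for alpha in (None, g["alpha"]):
            for snr in g["snr_values"]:
                conds.append(dict(base, alpha=alpha, snr_db=snr))
        return conds
    if preset == "denoising":
        return _conditions("noise", g)
    raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_METHODS)}")


PRESET_METHODS: Dict[str, List[str]] = {
    "noise_free": ALL_METHODS,
    "unequal_variance": ALL_METHODS,
    "d_sweep": CORE_METHODS,
    "alpha_sweep": CORE_METHODS,
    "data_amount": CORE_METHODS,
    "noise": CORE_METHODS,
    "denoising": CORE_METHODS,
}

PRESET_DEFAULT_N: Dict[str, int] = {
    "noise_free": 10,
    "unequal_variance": 10,
    "d_sweep": 3,
    "alpha_sweep": 10,
    "data_amount": 10,
    "noise": 10,
    "denoising": 10,
}

PRESETS = sorted(PRESET_METHODS)


# ---------------------------------------------------------------------------
# Sweep runner
# ---------------------------------------------------------------------------

def _run_cell(
    samples: np.ndarray, method: str, seed: int
) -> float:
    return ESTIMATORS[method](samples, seed)


def run_sweep(
    preset: str,
    scale: Optional[Dict[str, Any]] = None,
    seed: int = 0,
) -> SweepResult:
    """Run one benchmark preset.

    ``scale`` may override any grid key (``d_values``, ``alpha_values``,
    ``snr_values``, ``M_values``, ``N_values``, scalar ``d``/``M``/``N``/
    ``alpha``), the replication count ``n``, the ``methods`` list, and
    ``jae_max_epochs`` for the denoising preset.  Per-cell failures are
    recorded with a reason and never abort the sweep.
    """
    g = _merge_scale(scale)
    conditions = _conditions(preset, g)
    methods = list(g.get("methods", PRESET_METHODS[preset]))
    n = int(g.get("n", PRESET_DEFAULT_N[preset]))
    rows: List[Dict[str, Any]] = []
    seeds: List[int] = []
    for ci_idx, cond in enumerate(conditions):
        for rep in range(n):
            rep_seed = child_seed(seed, f"{preset}/cond{ci_idx}", rep)
            seeds.append(rep_seed)
            config = SimulationConfig(
                d=cond["d"], M=cond["M"], N=cond["N"],
                alpha=cond["alpha"], snr_db=cond["snr_db"],
                channel_scale_range=(1.0, 10.0) if cond["rescaled"] else None,
                seed=rep_seed,
            )
            try:
                ds = simulate_dataset(config)
            except Exception as err:  # pragma: no cover - defensive
                for method in methods:
                    rows.append(
                        dict(cond, replication=rep, seed=rep_seed, method=method,
                             estimate=np.nan, failed=True, reason=str(err))
                    )
                continue
            if preset == "denoising":
                rows.extend(
                    _denoising_cells(ds, cond, rep, rep_seed, methods, g)
                )
                continue
            samples = ds.observed.as_samples()
            for method in methods:
                try:
                    value = _run_cell(
                        samples, method, child_seed(rep_seed, f"est/{method}")
                    )
                    rows.append(
                        dict(cond, replication=rep, seed=rep_seed, method=method,
                             estimate=value, failed=False, reason="")
                    )
                except Exception as err:
                    rows.append(
                        dict(cond, replication=rep, seed=rep_seed, method=method,
                             estimate=np.nan, failed=True, reason=str(err))
                    )
    table = pd.DataFrame(rows)
    return SweepResult(
        preset=preset, table=table, n_replications=n, master_seed=seed, seeds=seeds
    )


def _denoising_cells(ds, cond, rep, rep_seed, methods, g):
    """Denoising preset: VAF of both denoisers vs the noise-free reference,
    then estimates on the branch-appropriate denoised signals (PCA-denoised
    for linear conditions, JAE-denoised for nonlinear ones, mirroring the
    study's usage)."""
    rows = []
    try:
        D = upper_bound_dimension(ds.observed, seed=child_seed(rep_seed, "pa_bound"))
        pca_res = pca_denoise(ds.observed, D, reference=ds.clean)
        hyper = JAEHyperparams(
            bottleneck_D=D,
            max_epochs=int(g.get("jae_max_epochs", 2000)),
            seed=child_seed(rep_seed, "jae"),
        )
        model = train_jae(ds.observed, hyper)
        jae_res = jae_denoise(model, ds.observed, reference=ds.clean)
    except Exception as err:
        for label in ["VAF_PCA", "VAF_JAE"] + methods:
            rows.append(
                dict(cond, replication=rep, seed=rep_seed, method=label,
                     estimate=np.nan, failed=True, reason=str(err))
            )
        return rows
    rows.append(dict(cond, replication=rep, seed=rep_seed, method="VAF_PCA",
                     estimate=pca_res.vaf_vs_reference, failed=False, reason=""))
    rows.append(dict(cond, replication=rep, seed=rep_seed, method="VAF_JAE",
                     estimate=jae_res.vaf_vs_reference, failed=False, reason=""))
    denoised = (jae_res if cond["alpha"] is not None else pca_res).denoised
    samples = denoised.as_samples()
    for method in methods:
        try:
            value = _run_cell(samples, method, child_seed(rep_seed, f"est/{method}"))
            rows.append(dict(cond, replication=rep, seed=rep_seed, method=method,
                             estimate=value, failed=False, reason=""))
        except Exception as err:
            rows.append(dict(cond, replication=rep, seed=rep_seed, method=method,
                             estimate=np.nan, failed=True, reason=str(err)))
    return rows
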