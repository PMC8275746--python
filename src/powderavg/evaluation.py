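"""Fidelity metrics, Monte-Carlo experiment grid and normality screening.

Two scalar measures quantify how well an estimated powder average tracks
the closed-form gold standard over the experiment's 8 nonzero b-shells
and 3 dispersion levels:

* ``d1`` - mean absolute deviation over all (b, kappa) cells;
* ``d2`` - Pearson correlation between the b-value and the
  kappa-averaged signed bias, i.e. whether the error grows (or shrinks)
  systematically with diffusion weighting.

:func:`run_experiment` drives the full simulation grid: for each noise
realization it synthesizes signals per dispersion level, adds noise,
applies every configured estimator and computes (d1, d2) per method and
noise level.  :func:`ad_test` is a composite-normality Anderson-Darling
test (mean and variance estimated) used to screen the distribution of
the averaged signals across realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .mapmri import MapMriModel
from .sampling import GradientScheme
from .shell import average_all_shells
from .simulate import (
    KAPPA_LEVELS,
    SIGMA_LEVELS,
    SignalArray,
    TissueModel,
    add_noise,
    ground_truth_average,
    simulate_signal,
)

__all__ = [
    "MetricPair",
    "MethodSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "ADResult",
    "compute_d1",
    "compute_d2",
    "ad_test",
    "run_experiment",
]


@dataclass(frozen=True)
class MetricPair:
    d1: float
    d2: float

    def __post_init__(self):
        if self.d1 < 0:
            raise ValueError("d1 is a mean absolute error, must be >= 0")
        if not -1.0 - 1e-12 <= self.d2 <= 1.0 + 1e-12:
            raise ValueError("d2 is a correlation, must lie in [-1, 1]")


def compute_d1(est: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute deviation of the estimates from the gold standard.

    ``est`` has shape (n_b, n_kappa) - one powder-average estimate per
    b-shell and dispersion level; ``gt`` has shape (n_b,) and is shared
    across dispersion levels (the closed form does not depend on the
    ODF).  With the study grid of 8 b-values and 3 kappas the
    normalization is the 1/24 of the experiment definition.
    """
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if est.ndim != 2 or est.shape[0] != gt.shape[0]:
        raise ValueError("est must be (n_b, n_kappa) matching gt length")
    return float(np.mean(np.abs(est - gt[:, None])))


def compute_d2(est: np.ndarray, gt: np.ndarray, b_values: np.ndarray) -> float:
    """Pearson correlation between b and the mean signed bias.

    ``eps_j = mean_k (est[j, k] - gt[j])``; returns ``corr(b_j, eps_j)``
    and 0 (by convention) when the bias has zero variance - a constant
    offset carries no b-dependent trend.
    """
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if est.ndim != 2 or est.shape[0] != gt.shape[0] or est.shape[0] != b.shape[0]:
        raise ValueError("shape mismatch between est, gt and b_values")
    if len(b) < 3:
        raise ValueError("need at least 3 b-values for a correlation")
    eps = np.mean(est - gt[:, None], axis=1)
    # constant bias (up to rounding) carries no b-dependent trend
    if np.std(eps) <= 1e-12 * (1.0 + np.abs(eps).max()):
        return 0.0
    return float(pearsonr(b, eps)[0])


@dataclass(frozen=True)
class ADResult:
    statistic: float  # A^2, uncorrected
    p_value: float
    reject_at_5pct: bool


def ad_test(samples, alpha: float = 0.05) -> ADResult:
    """Anderson-Darling test of composite normality.

    Mean and variance are estimated from the sample (case 3);
    the small-sample correction ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)``
    and the standard p-value approximation are applied, matching common
    'adtest' implementations.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    z = norm.cdf((x - np.mean(x)) / np.std(x, ddof=1))
    z = np.clip(z, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1])))
    zc = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if zc >= 0.6:
        p = np.exp(1.2937 - 5.709 * zc + 0.0186 * zc**2)
    elif zc > 0.34:
        p = np.exp(0.9177 - 4.279 * zc - 1.38 * zc**2)
    elif zc > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * zc - 59.938 * zc**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * zc - 223.73 * zc**2)
    p = float(min(max(p, 0.0), 1.0))
    return ADResult(float(a2), p, p < alpha)


@dataclass(frozen=True)
class MethodSpec:
    """One powder-averaging technique in an experiment.

    ``kind`` is a shell method tag (arithmetic/lebedev/sh/tensor/
    knutsson) or a MAP family tag (map/mapl), with per-method options.
    """

    kind: str
    L: int = 6
    k_max: int | None = None
    n_max: int = 8
    mode: str | None = None  # MAP fit mode override

    @property
    def tag(self) -> str:
        if self.kind == "sh":
            return f"sh(L={self.L})"
        if self.kind in ("map", "mapl"):
            return f"{self.kind}(n_max={self.n_max})"
        return self.kind

    @property
    def is_map(self) -> bool:
        return self.kind in ("map", "mapl")


@dataclass(frozen=True)
class ExperimentConfig:
    scheme: GradientScheme
    methods: tuple
    kappas: tuple = KAPPA_LEVELS
    sigmas: tuple = SIGMA_LEVELS
    noise_model: str = "gaussian"
    n_realizations: int = 100
    master_seed: int = 0
    b_eval: tuple = (1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0)
    # optional callable kappa -> TissueModel (e.g. crossing configurations)
    model_factory: object = None

    def __post_init__(self):
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("noise levels must be >= 0")
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "kappas", tuple(self.kappas))
        object.__setattr__(self, "sigmas", tuple(self.sigmas))
        object.__setattr__(self, "b_eval", tuple(float(b) for b in self.b_eval))


@dataclass
class ExperimentResult:
    """Tidy per-realization metrics plus aggregates and signal samples."""

    records: pd.DataFrame  # columns: method, sigma, realization, d1, d2
    aggregates: pd.DataFrame  # columns: method, sigma, d1_mean, d1_std, d2_mean, d2_std
    samples: dict  # (method_tag, sigma) -> array (n_real, n_b, n_kappa)
    config: ExperimentConfig

    def mean_d1(self, method_tag: str, sigma: float) -> float:
        a = self.aggregates
        row = a[(a.method == method_tag) & (np.isclose(a.sigma, sigma))]
        return float(row.d1_mean.iloc[0])

    def mean_d2(self, method_tag: str, sigma: float) -> float:
        a = self.aggregates
        row = a[(a.method == method_tag) & (np.isclose(a.sigma, sigma))]
        return float(row.d2_mean.iloc[0])

    def normality_screen(self, alpha: float = 0.05) -> pd.DataFrame:
        """Anderson-Darling p-values of the averaged signal across
        realizations, one row per (method, sigma, b, kappa) cell."""
        rows = []
        for (tag, sigma), arr in self.samples.items():
            n_real, n_b, n_k = arr.shape
            for jb in range(n_b):
                for jk in range(n_k):
                    res = ad_test(arr[:, jb, jk], alpha)
                    rows.append({
                        "method": tag, "sigma": sigma,
                        "b": self.config.b_eval[jb],
                        "kappa": self.config.kappas[jk],
                        "A2": res.statistic, "p_value": res.p_value,
                        "reject": res.reject_at_5pct,
                    })
        return pd.DataFrame(rows)


def _cell_rng(master_seed: int, realization: int, i_kappa: int, i_sigma: int):
    """Independent stream per (realization, kappa, sigma) cell, so adding
    or removing methods never perturbs the noise draws."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(realization, i_kappa, i_sigma))
    return np.random.default_rng(ss)


def _apply_method(method: MethodSpec, scheme: GradientScheme,
                  noisy: SignalArray, b_eval) -> np.ndarray | None:
    """One method on one noisy realization; None if incompatible."""
    if method.is_map:
        mode = method.mode or ("laplacian" if method.kind == "mapl" else "constrained")
        try:
            model = MapMriModel(noisy, scheme, n_max=method.n_max)
        except ValueError:
            return None  # e.g. nonpositive MD under extreme noise
        fit = model.fit(mode=mode)
        return fit.powder_average(np.asarray(b_eval))
    if not scheme.is_shelled:
        return None
    try:
        pa = average_all_shells(scheme, noisy, method.kind, L=method.L,
                                k_max=method.k_max)
    except ValueError:
        return None
    return pa.s_bar


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the Monte-Carlo comparison grid.

    For every realization and dispersion level, noise of each requested
    level is added to the (precomputed) noise-free signals; every method
    produces powder-average estimates at the evaluation b-values, from
    which per-realization (d1, d2) are formed against the closed-form
    gold standard.  The same noise draws are shared across methods
    (variance reduction for the method comparison).  Incompatible
    (method, scheme) cells are skipped, not errors.
    """
    scheme = config.scheme
    b_eval = np.asarray(config.b_eval)
    gt = ground_truth_average(b_eval)
    factory = config.model_factory or (lambda kappa: TissueModel.single(kappa))
    noise_free = {k: simulate_signal(scheme, factory(k)) for k in config.kappas}

    est_store: dict = {
        (m.tag, s): np.full((config.n_realizations, len(b_eval), len(config.kappas)), np.nan)
        for m in config.methods for s in config.sigmas
    }
    skipped = set()
    for r in range(config.n_realizations):
        for ik, kappa in enumerate(config.kappas):
            for isg, sigma in enumerate(config.sigmas):
                rng = _cell_rng(config.master_seed, r, ik, isg)
                noisy = add_noise(noise_free[kappa], sigma,
                                  config.noise_model if sigma > 0 else "gaussian",
                                  seed=rng)
                for m in config.methods:
                    est = _apply_method(m, scheme, noisy, b_eval)
                    if est is None:
                        skipped.add((m.tag, sigma))
                        continue
                    est_store[(m.tag, sigma)][r, :, ik] = est

    rows = []
    for m in config.methods:
        for sigma in config.sigmas:
            if (m.tag, sigma) in skipped:
                continue
            arr = est_store[(m.tag, sigma)]
            for r in range(config.n_realizations):
                est = arr[r]
                if np.any(np.isnan(est)):
                    continue
                rows.append({
                    "method": m.tag, "sigma": sigma, "realization": r,
                    "d1": compute_d1(est, gt),
                    "d2": compute_d2(est, gt, b_eval),
                })
    records = pd.DataFrame(rows)
    if len(records):
        aggregates = (
            records.groupby(["method", "sigma"], as_index=False)
            .agg(d1_mean=("d1", "mean"), d1_std=("d1", "std"),
                 d2_mean=("d2", "mean"), d2_std=("d2", "std"))
        )
    else:
        aggregates = pd.DataFrame(columns=["method", "sigma", "d1_mean",
                                           "d1_std", "d2_mean", "d2_std"])
    samples = {k: v for k, v in est_store.items() if k not in skipped}
    return ExperimentResult(records, aggregates, samples, config)
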