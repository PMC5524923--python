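"""Posterior credible intervals and permutation tests for growth parameters.

The posterior is defined over the structural growth-law parameters theta
only: latent anchor times and the error variance are profiled out of the
likelihood (the same profile likelihood maximised during fitting), and the
prior is log-uniform (flat in log theta) over the law's parameter bounds.
Sampling uses adaptive random-walk Metropolis on log theta: several chains
start jittered around the MLE, the proposal scale adapts toward a ~30%
acceptance rate during burn-in and is then frozen, and convergence is
summarised by the split-chain potential scale reduction factor (R-hat).

Group differences in growth rate are tested by permutation: tumour-level
labels are shuffled (never measurements within a series), each relabelled
cohort is refitted per group, and the absolute difference in fitted growth
rates is compared with its permutation distribution using the add-one
convention p = (1 + #{perm >= observed}) / (1 + n_perm), which cannot
return p = 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .growth_models import GrowthModelSpec
from .likelihood import (
    FitConfig,
    FitResult,
    TumourSeries,
    fit_model,
    profiled_neg_loglik,
)

__all__ = [
    "CredibleInterval",
    "PermutationResult",
    "McmcConfig",
    "PosteriorSamples",
    "sample_posterior",
    "credible_interval",
    "permutation_test",
    "rate_difference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CredibleInterval:
    """Central (equal-tailed) posterior interval for one parameter."""

    parameter: str
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not self.lower <= self.upper:
            raise ValueError("lower must not exceed upper")


@dataclass
class PermutationResult:
    observed: float
    perm_stats: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int
    group_label: str
    groups: Tuple[str, str]


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_steps: int = 1500  # post-burn-in steps per chain
    burn_in: int = 500
    seed: int = 0
    target_accept: float = 0.3
    init_jitter: float = 0.05  # sd of log-scale jitter around the MLE
    rhat_threshold: float = 1.05
    priors: Optional[Tuple[Tuple[float, float], ...]] = None  # natural scale
    #: Integrate the error variance out on the residual degrees of freedom
    #: (n - number of profiled anchors) instead of plugging in its MLE; the
    #: plug-in profile over-sharpens the posterior when most series are
    #: short (each profiled anchor absorbs one residual df).
    df_adjusted: bool = True


@dataclass
class PosteriorSamples:
    """Pooled post-burn-in draws of theta (natural scale) with diagnostics."""

    spec: GrowthModelSpec
    samples: np.ndarray  # (n_chains * n_steps, k)
    chains: np.ndarray = field(repr=False)  # (n_chains, n_steps, k)
    accept_rate: float
    rhat: np.ndarray
    converged: bool

    def parameter(self, name: str) -> np.ndarray:
        return self.samples[:, self.spec.param_names.index(name)]


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter.

    ``chains``: (n_chains, n_steps, k).  Each chain is split in half, giving
    2*n_chains sequences; R-hat compares between- to within-sequence
    variance.  Values near 1 indicate mixing.
    """
    n_chains, n_steps, k = chains.shape
    half = n_steps // 2
    seq = np.concatenate([chains[:, :half, :], chains[:, half : 2 * half, :]], axis=0)
    m, n = seq.shape[0], seq.shape[1]
    means = seq.mean(axis=1)  # (m, k)
    variances = seq.var(axis=1, ddof=1)  # (m, k)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def sample_posterior(
    series_set: Sequence[TumourSeries],
    spec: GrowthModelSpec,
    fit: FitResult,
    config: Optional[McmcConfig] = None,
    log_prob: Optional[Callable[[np.ndarray], float]] = None,
) -> PosteriorSamples:
    """Draw from the profile-likelihood posterior of theta by adaptive
    random-walk Metropolis.

    ``log_prob`` may override the target (used by the conjugate-toy checks);
    by default it is the profile log-likelihood plus a log-uniform prior on
    the law's bounds (or ``config.priors``).  Reproducible given the seed;
    non-convergence (split R-hat above threshold) triggers a warning but the
    samples are still returned.
    """
    config = config or McmcConfig()
    k = spec.k
    bounds = np.array(config.priors if config.priors is not None else spec.bounds,
                      dtype=float)
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    if log_prob is None:
        neg = profiled_neg_loglik(
            series_set, spec, fit.config, df_adjusted=config.df_adjusted
        )

        def log_prob(log_theta: np.ndarray) -> float:
            if np.any(log_theta < log_lo) or np.any(log_theta > log_hi):
                return -np.inf
            return -neg(np.exp(log_theta))

    rng = np.random.default_rng(config.seed)
    centre = np.log(np.asarray(fit.theta_hat, dtype=float))
    centre = np.clip(centre, log_lo, log_hi)

    n_total = config.burn_in + config.n_steps
    chains = np.empty((config.n_chains, config.n_steps, k))
    n_accept = 0
    n_prop = 0
    for c in range(config.n_chains):
        x = centre + config.init_jitter * rng.standard_normal(k)
        x = np.clip(x, log_lo, log_hi)
        lp = log_prob(x)
        if not np.isfinite(lp):
            x = centre.copy()
            lp = log_prob(x)
        scale = np.full(k, 0.1)
        accept_window = 0
        for step in range(n_total):
            prop = x + scale * rng.standard_normal(k)
            lp_prop = log_prob(prop)
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accept_window += 1
                if step >= config.burn_in:
                    n_accept += 1
            if step >= config.burn_in:
                n_prop += 1
                chains[c, step - config.burn_in] = x
            elif (step + 1) % 50 == 0:
                # Robbins-Monro-style scale adaptation during burn-in only.
                rate = accept_window / 50.0
                scale *= math.exp(rate - config.target_accept)
                accept_window = 0

    rhat = split_rhat(chains)
    converged = bool(np.all(rhat < config.rhat_threshold))
    if not converged:
        warnings.warn(
            f"posterior sampling for {spec.name} may not have converged: "
            f"split R-hat = {np.round(rhat, 3).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    samples = np.exp(chains.reshape(-1, k))
    return PosteriorSamples(
        spec=spec,
        samples=samples,
        chains=np.exp(chains),
        accept_rate=n_accept / max(n_prop, 1),
        rhat=rhat,
        converged=converged,
    )


def credible_interval(
    samples: Sequence[float],
    level: float = 0.95,
    parameter: str = "",
    point: Optional[float] = None,
) -> CredibleInterval:
    """Central credible interval from posterior draws: the ((1-level)/2,
    1-(1-level)/2) empirical quantiles."""
    s = np.asarray(samples, dtype=float)
    if s.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if s.size < 100:
        raise ValueError(f"need >= 100 samples for a stable interval, got {s.size}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(s, [alpha, 1.0 - alpha])
    pt = float(np.median(s)) if point is None else float(point)
    pt_clipped = min(max(pt, lower), upper)
    return CredibleInterval(parameter, pt_clipped, float(lower), float(upper), level)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def rate_difference(
    series_a: Sequence[TumourSeries],
    series_b: Sequence[TumourSeries],
    spec: GrowthModelSpec,
    config: FitConfig,
) -> float:
    """|r_hat_A - r_hat_B| from independent per-group fits; the default
    permutation statistic (the growth rate is the first parameter of every
    law here)."""
    fa = fit_model(series_a, spec, config)
    fb = fit_model(series_b, spec, config)
    return abs(float(fa.theta_hat[0]) - float(fb.theta_hat[0]))


def permutation_test(
    series_set: Sequence[TumourSeries],
    group_label: str,
    spec: GrowthModelSpec,
    statistic: Optional[Callable] = None,
    n_perm: int = 999,
    seed: int = 0,
    config: Optional[FitConfig] = None,
) -> PermutationResult:
    """Tumour-level permutation test for a group difference in growth rate.

    ``group_label`` is a covariate name (sex, ploidy or location); series
    labelled ``unknown`` are dropped and exactly two groups must remain.
    Labels are permuted across tumours (whole series keep their measurements
    together).  Both group fits reuse the unpermuted MLE as a warm start.
    """
    config = config or FitConfig()
    labelled = [s for s in series_set if s.covariates[group_label] != "unknown"]
    groups = sorted({s.covariates[group_label] for s in labelled})
    if len(groups) != 2:
        raise ValueError(
            f"permutation test needs exactly 2 groups for {group_label!r}, "
            f"found {groups}"
        )
    labels = np.array([s.covariates[group_label] for s in labelled])
    split = lambda lab: (
        [s for s, g in zip(labelled, lab) if g == groups[0]],
        [s for s, g in zip(labelled, lab) if g == groups[1]],
    )
    ga, gb = split(labels)
    for name, grp in zip(groups, (ga, gb)):
        n = sum(s.n_obs for s in grp)
        if n < spec.k + 2:
            raise ValueError(
                f"group {name!r} too small to fit {spec.name}: {n} measurements"
            )

    stat = statistic or rate_difference
    observed = stat(ga, gb, spec, config)

    # Warm-start permuted refits at the pooled MLE; fewer cold starts needed.
    pooled = fit_model(labelled, spec, config)
    warm_cfg = FitConfig(
        **{**config.__dict__, "warm_start": pooled.theta_hat,
           "multistart": max(2, config.multistart // 4)}
    )

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(labels)
        pa, pb = split(perm)
        perm_stats[p] = stat(pa, pb, spec, warm_cfg)
    p_value = (1.0 + np.sum(perm_stats >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed=float(observed),
        perm_stats=perm_stats,
        p_value=float(p_value),
        n_perm=n_perm,
        seed=seed,
        group_label=group_label,
        groups=(groups[0], groups[1]),
    )
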