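"""Lognormal-error likelihood with latent per-tumour anchor times.

The observation model: tumour ``i`` measured for the ``j``-th time has volume
``V_ij`` at time ``t_ij`` (days since that tumour's first capture, so
``t_i1 = 0``).  Log-volumes are normally distributed around the growth-law
curve,

    log V_ij ~ Normal(mu = log V(t_ij; theta, t_i0), sigma^2 = epsilon),

where ``t_i0`` is the latent per-tumour time (relative to first capture, may
be negative) at which the tumour reached the reference volume V0, and
``epsilon`` is a single error variance shared across all tumours.  The
lognormal error absorbs measurement error and tumour-to-tumour rate
variation multiplicatively.

Fitting is a nested optimisation: an outer multi-start bounded search over
the structural parameters ``theta`` (on log scale), an inner exact or
numeric profile of each ``t_i0`` (they decouple across tumours), and a
closed-form profile of ``epsilon`` (the MLE of a normal variance is the mean
squared log-residual).  Neither ``t_i0`` nor ``epsilon`` counts toward the
parameter number ``k`` used by AICc; only ``theta`` does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .growth_models import (
    DEFAULT_V0,
    EPSILON_FLOOR,
    AnchorConvention,
    DomainError,
    GrowthModelSpec,
    model_solution,
    solution_curve,
    time_to_volume,
    validate_theta,
)

__all__ = [
    "Measurement",
    "TumourSeries",
    "FitConfig",
    "FitResult",
    "log_likelihood",
    "profile_t0",
    "profile_epsilon",
    "fit_model",
]

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

#: Search bracket for latent anchor times, days relative to first capture.
#: The epidemic at the study site began in 2006, ~10 years before the last
#: capture, so +/- 3000 days is a hard biological bound.
DEFAULT_T0_BRACKET = (-3000.0, 3000.0)


@dataclass(frozen=True)
class Measurement:
    """One capture event: time (days since the tumour's first capture) and
    volume (cm^3)."""

    t: float
    V: float

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError(f"volume must be positive, got {self.V}")
        if self.t < 0:
            raise ValueError("time must be >= 0 relative to first capture")


UNKNOWN = "unknown"


@dataclass
class TumourSeries:
    """Ordered repeat measurements of one tumour, with host covariates."""

    tumour_id: str
    host_id: str
    t: np.ndarray  # days since first capture, strictly increasing, t[0] == 0
    V: np.ndarray  # volumes, cm^3
    sex: str = UNKNOWN
    ploidy: str = UNKNOWN  # diploid | tetraploid | unknown
    location: str = UNKNOWN  # dermal | mucosal | unknown

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.size == 0:
            raise ValueError(f"tumour {self.tumour_id}: needs >= 1 measurement")
        if self.t.shape != self.V.shape:
            raise ValueError(f"tumour {self.tumour_id}: t/V length mismatch")
        if self.t[0] != 0.0:
            raise ValueError(
                f"tumour {self.tumour_id}: first measurement must be at t = 0"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"tumour {self.tumour_id}: times must be strictly increasing"
            )
        if np.any(self.V <= 0):
            raise ValueError(f"tumour {self.tumour_id}: volumes must be positive")

    @property
    def n_obs(self) -> int:
        return self.t.size

    @property
    def measurements(self) -> List[Measurement]:
        return [Measurement(float(ti), float(vi)) for ti, vi in zip(self.t, self.V)]

    @property
    def covariates(self) -> Dict[str, str]:
        return {"sex": self.sex, "ploidy": self.ploidy, "location": self.location}


@dataclass
class FitConfig:
    """Settings for :func:`fit_model`.

    multistart:      number of Latin-hypercube starting points for theta.
    seed:            RNG seed for start placement (deterministic fits).
    min_points_per_tumour: series with fewer measurements are dropped before
                     fitting.  Singletons (the default minimum, 1) contribute
                     a zero residual after t0 profiling and so influence only
                     the observation count in AICc.
    V0:              anchor volume, cm^3 (cosmetic; shifts t0 only).
    t0_bracket:      search interval for anchor times, days.
    bounds:          optional per-parameter (lo, hi) overriding the model's.
    eps_floor:       lower bound on the profiled error variance.
    coarse_step / fine_step: grid resolutions (days) for the vectorised t0
                     profile used inside the outer search.
    warm_start:      optional theta used as an additional starting point.
    """

    multistart: int = 20
    seed: int = 0
    min_points_per_tumour: int = 1
    V0: float = DEFAULT_V0
    t0_bracket: Tuple[float, float] = DEFAULT_T0_BRACKET
    bounds: Optional[Tuple[Tuple[float, float], ...]] = None
    eps_floor: float = EPSILON_FLOOR
    coarse_step: float = 10.0
    fine_step: float = 0.1
    warm_start: Optional[Sequence[float]] = None
    maxiter: int = 400


@dataclass
class FitResult:
    """Maximum-likelihood fit of one growth law to a cohort."""

    spec: GrowthModelSpec
    theta_hat: np.ndarray
    t0_hat: Dict[str, float]  # per-tumour anchor days (may be negative)
    epsilon_hat: float  # variance of log-volume residuals
    loglik: float
    n_obs: int
    n_tumours: int
    aicc: float
    converged: bool
    config: FitConfig = field(repr=False, default_factory=FitConfig)

    def theta_dict(self) -> Dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.theta_hat)))


# ---------------------------------------------------------------------------
# Cohort arrays: flat representation used by the vectorised profilers
# ---------------------------------------------------------------------------

class _CohortArrays:
    """Concatenated (t, log V) arrays with per-tumour segment bookkeeping."""

    def __init__(self, series_set: Sequence[TumourSeries]):
        if not series_set:
            raise ValueError("empty cohort")
        self.series_set = list(series_set)
        self.t = np.concatenate([s.t for s in series_set])
        self.y = np.log(np.concatenate([s.V for s in series_set]))
        counts = np.array([s.n_obs for s in series_set])
        self.counts = counts
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.n_obs = int(counts.sum())
        self.n_tumours = len(series_set)
        # Within-tumour centred moments for the exponential fast path.
        t_mean = np.add.reduceat(self.t, self.starts) / counts
        y_mean = np.add.reduceat(self.y, self.starts) / counts
        self.t_mean, self.y_mean = t_mean, y_mean
        dt = self.t - np.repeat(t_mean, counts)
        dy = self.y - np.repeat(y_mean, counts)
        self.S_dt2 = float(dt @ dt)
        self.S_dydt = float(dy @ dt)
        self.S_dy2 = float(dy @ dy)


def _segment_sums(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Row-segment sums of a (n_obs, m) matrix -> (n_segments, m)."""
    return np.add.reduceat(x, starts, axis=0)


def _residual_sq_matrix(
    arrays: _CohortArrays,
    spec: GrowthModelSpec,
    theta: np.ndarray,
    V0: float,
    t0_grid: np.ndarray,
) -> np.ndarray:
    """Squared log-residuals for every observation x candidate t0.

    Candidate anchors outside a law's domain (nan / non-positive predicted
    volume) get +inf so they are never selected.
    """
    dt = arrays.t[:, None] - t0_grid[None, :]
    pred = solution_curve(spec, theta, V0, dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        logpred = np.log(pred)
    res2 = (arrays.y[:, None] - logpred) ** 2
    return np.where(np.isfinite(res2), res2, np.inf)


def _profile_t0_vectorised(
    arrays: _CohortArrays,
    spec: GrowthModelSpec,
    theta: np.ndarray,
    V0: float,
    bracket: Tuple[float, float],
    coarse_step: float,
    fine_step: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Profile every tumour's anchor time on a coarse->fine grid.

    Returns (t0_hat, ss) per tumour.  A final parabolic interpolation around
    the fine-grid minimum gives ~1e-3 day placement on smooth objectives.
    Tumours whose entire grid is invalid get ss = +inf.
    """
    if spec.name == "exponential":
        r = theta[0]
        t0 = arrays.t_mean - (arrays.y_mean - math.log(V0)) / r
        dt = arrays.t - np.repeat(arrays.t_mean, arrays.counts)
        dy = arrays.y - np.repeat(arrays.y_mean, arrays.counts)
        res = dy - r * dt
        ss = np.add.reduceat(res * res, arrays.starts)
        return t0, ss

    lo, hi = bracket
    coarse = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    ss_c = _segment_sums(
        _residual_sq_matrix(arrays, spec, theta, V0, coarse), arrays.starts
    )
    best = np.argmin(ss_c, axis=1)
    centres = coarse[best]
    all_invalid = ~np.isfinite(ss_c[np.arange(arrays.n_tumours), best])

    # Fine pass: one shared offset grid around each tumour's coarse minimum.
    offsets = np.arange(-coarse_step, coarse_step + 0.5 * fine_step, fine_step)
    t0_fine = centres[:, None] + offsets[None, :]  # (n_tum, n_off)
    dt = arrays.t[:, None] - np.repeat(t0_fine, arrays.counts, axis=0)
    pred = solution_curve(spec, theta, V0, dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        res2 = (arrays.y[:, None] - np.log(pred)) ** 2
    res2 = np.where(np.isfinite(res2), res2, np.inf)
    ss_f = _segment_sums(res2, arrays.starts)
    jbest = np.argmin(ss_f, axis=1)
    idx = np.arange(arrays.n_tumours)
    t0_hat = t0_fine[idx, jbest]
    ss = ss_f[idx, jbest]

    # Parabolic refinement where the minimum is interior and finite.
    interior = (jbest > 0) & (jbest < len(offsets) - 1) & np.isfinite(ss)
    if np.any(interior):
        jm = jbest[interior]
        f0 = ss_f[idx[interior], jm - 1]
        f1 = ss_f[idx[interior], jm]
        f2 = ss_f[idx[interior], jm + 1]
        denom = f0 - 2 * f1 + f2
        ok = np.isfinite(f0) & np.isfinite(f2) & (denom > 0)
        shift = np.zeros_like(f1)
        shift[ok] = 0.5 * (f0[ok] - f2[ok]) / denom[ok] * fine_step
        shift = np.clip(shift, -fine_step, fine_step)
        t0_new = t0_hat.copy()
        t0_new[interior] = t0_hat[interior] + shift
        ss_new = _ss_at_t0(arrays, spec, theta, V0, t0_new)
        improve = ss_new <= ss
        t0_hat = np.where(improve, t0_new, t0_hat)
        ss = np.where(improve, ss_new, ss)

    ss[all_invalid] = np.inf
    return t0_hat, ss


def _ss_at_t0(
    arrays: _CohortArrays,
    spec: GrowthModelSpec,
    theta: np.ndarray,
    V0: float,
    t0: np.ndarray,
) -> np.ndarray:
    """Per-tumour sum of squared log-residuals at given anchor times."""
    dt = arrays.t - np.repeat(t0, arrays.counts)
    pred = solution_curve(spec, theta, V0, dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = arrays.y - np.log(pred)
    res2 = np.where(np.isfinite(res), res * res, np.inf)
    return np.add.reduceat(res2, arrays.starts)


# ---------------------------------------------------------------------------
# Public likelihood pieces
# ---------------------------------------------------------------------------

def log_likelihood(
    series_set: Sequence[TumourSeries],
    spec: GrowthModelSpec,
    theta: Sequence[float],
    t0_vec: Sequence[float],
    epsilon: float,
    V0: float = DEFAULT_V0,
) -> float:
    """Sum over all measurements of the normal log-density of log V_ij around
    the growth-law curve (variance ``epsilon``).  Larger is better.

    Anchor placements that push any observation outside the law's domain
    yield ``-inf`` (a rejected point), not an exception.
    """
    th = validate_theta(spec, theta)
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    t0_vec = np.asarray(t0_vec, dtype=float)
    if t0_vec.shape != (len(series_set),):
        raise ValueError("t0_vec length must equal the number of tumours")
    arrays = _CohortArrays(series_set)
    ss = _ss_at_t0(arrays, spec, th, V0, t0_vec)
    total = float(ss.sum())
    if not np.isfinite(total):
        return -np.inf
    n = arrays.n_obs
    return -0.5 * n * (LOG_2PI + math.log(epsilon)) - total / (2.0 * epsilon)


def profile_t0(
    series: TumourSeries,
    spec: GrowthModelSpec,
    theta: Sequence[float],
    V0: float = DEFAULT_V0,
    bracket: Tuple[float, float] = DEFAULT_T0_BRACKET,
) -> Tuple[float, float]:
    """Anchor time minimising this tumour's sum of squared log-residuals.

    Because the error variance is shared across tumours, this also maximises
    the tumour's likelihood contribution for any epsilon.  Exponential series
    have the closed form t0 = mean_j[t_j - (log V_j - log V0)/r]; a
    single-measurement series is solved by inverting the growth curve through
    its one point; everything else uses a coarse-to-fine grid search refined
    by bounded Brent minimisation.

    Returns ``(t0_hat, sum_of_squared_log_residuals)``.
    """
    th = validate_theta(spec, theta)
    y = np.log(series.V)
    logV0 = math.log(V0)

    if spec.name == "exponential":
        r = th[0]
        t0 = float(np.mean(series.t - (y - logV0) / r))
        res = y - (logV0 + r * (series.t - t0))
        return t0, float(res @ res)

    if series.n_obs == 1:
        try:
            reach = time_to_volume(spec, th, AnchorConvention(V0=V0), float(series.V[0]))
            return float(series.t[0] - reach), 0.0
        except DomainError:
            pass  # fall through to the grid (best achievable residual > 0)

    arrays = _CohortArrays([series])

    def ss_of(t0: float) -> float:
        return float(_ss_at_t0(arrays, spec, th, V0, np.array([t0]))[0])

    t0_grid, ss_grid = _profile_t0_vectorised(
        arrays, spec, th, V0, bracket, coarse_step=10.0, fine_step=0.1
    )
    t0_best, ss_best = float(t0_grid[0]), float(ss_grid[0])
    if not np.isfinite(ss_best):
        raise DomainError(
            f"tumour {series.tumour_id}: no valid anchor time in {bracket} "
            f"for {spec.name} at theta={th.tolist()}"
        )
    res = optimize.minimize_scalar(
        ss_of,
        bounds=(t0_best - 1.0, t0_best + 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if np.isfinite(res.fun) and res.fun <= ss_best:
        t0_best, ss_best = float(res.x), float(res.fun)
    return t0_best, ss_best


def profile_epsilon(
    log_residuals: Sequence[float], eps_floor: float = EPSILON_FLOOR
) -> float:
    """MLE of the shared error variance: mean squared log-residual, floored."""
    res = np.asarray(log_residuals, dtype=float)
    if res.size == 0:
        raise ValueError("at least one residual required")
    return max(float(np.mean(res**2)), eps_floor)


def _profiled_loglik(ss_total: float, n: int, eps_floor: float) -> Tuple[float, float]:
    """(loglik, epsilon_hat) after closed-form epsilon profiling."""
    if not np.isfinite(ss_total):
        return -np.inf, np.nan
    eps = max(ss_total / n, eps_floor)
    ll = -0.5 * n * (LOG_2PI + math.log(eps)) - ss_total / (2.0 * eps)
    return ll, eps


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _lhs_starts(
    log_bounds: np.ndarray, n: int, seed: int, warm: Optional[np.ndarray]
) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=log_bounds.shape[0], seed=seed)
    unit = sampler.random(n)
    starts = qmc.scale(unit, log_bounds[:, 0], log_bounds[:, 1])
    if warm is not None:
        starts = np.vstack([np.log(warm)[None, :], starts])
    return starts


def fit_model(
    series_set: Sequence[TumourSeries],
    spec: GrowthModelSpec,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Maximum-likelihood fit of one growth law to a cohort.

    Outer bounded Nelder-Mead over log-theta from Latin-hypercube starts;
    inner vectorised profile of every anchor time; closed-form profile of the
    error variance.  Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    kept = [s for s in series_set if s.n_obs >= config.min_points_per_tumour]
    dropped = len(series_set) - len(kept)
    if dropped:
        logger.info("fit_model(%s): dropped %d series below min_points_per_tumour=%d",
                    spec.name, dropped, config.min_points_per_tumour)
    if not kept:
        raise ValueError("no series left after filtering")
    arrays = _CohortArrays(kept)
    n = arrays.n_obs
    if n < spec.k + 2:
        raise ValueError(
            f"need at least k + 2 = {spec.k + 2} observations for AICc, got {n}"
        )

    bounds = np.array(config.bounds if config.bounds is not None else spec.bounds,
                      dtype=float)
    log_bounds = np.log(bounds)

    if spec.name == "exponential":
        # Profiled SS is exactly quadratic in r (within-tumour centring
        # absorbs every t0): SS(r) = S_dy2 - 2 r S_dydt + r^2 S_dt2.
        def neg_profiled(log_theta: np.ndarray) -> float:
            r = math.exp(log_theta[0])
            ss = arrays.S_dy2 - 2.0 * r * arrays.S_dydt + r * r * arrays.S_dt2
            ll, _ = _profiled_loglik(max(ss, 0.0), n, config.eps_floor)
            return -ll
    else:
        def neg_profiled(log_theta: np.ndarray) -> float:
            theta = np.exp(log_theta)
            _, ss = _profile_t0_vectorised(
                arrays, spec, theta, config.V0, config.t0_bracket,
                config.coarse_step, config.fine_step,
            )
            ll, _ = _profiled_loglik(float(ss.sum()), n, config.eps_floor)
            return -ll

    warm = None
    if config.warm_start is not None:
        warm = validate_theta(spec, config.warm_start)
    starts = _lhs_starts(log_bounds, config.multistart, config.seed, warm)

    best = None
    n_failed = 0
    for x0 in starts:
        try:
            res = optimize.minimize(
                neg_profiled,
                x0,
                method="Nelder-Mead",
                bounds=log_bounds,
                options={
                    "xatol": 1e-10,
                    "fatol": 1e-10,
                    "maxiter": config.maxiter * spec.k,
                },
            )
        except Exception:  # pragma: no cover - optimiser robustness
            n_failed += 1
            continue
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimisation starts failed for {spec.name}"
        )

    # exp/log round-trips can overshoot the bounds by an ulp; clip back.
    theta_hat = np.clip(np.exp(best.x), bounds[:, 0], bounds[:, 1])
    # Final accurate anchor profile at the optimum (Brent-polished per tumour).
    t0_hat_vec = np.empty(arrays.n_tumours)
    ss_total = 0.0
    for i, s in enumerate(kept):
        t0_i, ss_i = profile_t0(s, spec, theta_hat, config.V0, config.t0_bracket)
        t0_hat_vec[i] = t0_i
        ss_total += ss_i
    loglik, eps_hat = _profiled_loglik(ss_total, n, config.eps_floor)

    from .model_selection import aicc  # local import: avoids a module cycle

    return FitResult(
        spec=spec,
        theta_hat=theta_hat,
        t0_hat={s.tumour_id: float(t0) for s, t0 in zip(kept, t0_hat_vec)},
        epsilon_hat=eps_hat,
        loglik=loglik,
        n_obs=n,
        n_tumours=arrays.n_tumours,
        aicc=aicc(loglik, spec.k, n),
        converged=bool(best.success),
        config=config,
    )


def profiled_neg_loglik(
    series_set: Sequence[TumourSeries],
    spec: GrowthModelSpec,
    config: Optional[FitConfig] = None,
    df_adjusted: bool = False,
):
    """Return a callable theta -> -log target with t0 (and epsilon) profiled
    or marginalised out.  Used by the posterior sampler; shares the fast
    vectorised path.

    With ``df_adjusted=False`` this is the plain profile log-likelihood
    (epsilon plugged in at its MLE SS/n).  With ``df_adjusted=True`` epsilon
    is instead integrated out under a Jeffreys prior using the residual
    degrees of freedom nu = n - m (m = number of profiled anchor times),
    giving -log target = (nu/2) log SS(theta).  The adjustment compensates
    for the variance the m profiled anchors absorb — the plain profile
    treats the error variance as if estimated from n residuals when only
    n - m are free, which over-sharpens the posterior for small series.
    """
    config = config or FitConfig()
    arrays = _CohortArrays(series_set)
    n = arrays.n_obs
    nu = max(n - arrays.n_tumours, 1)
    floor_ss = config.eps_floor * n

    def _ss(theta: np.ndarray) -> float:
        if spec.name == "exponential":
            r = theta[0]
            return max(
                arrays.S_dy2 - 2.0 * r * arrays.S_dydt + r * r * arrays.S_dt2, 0.0
            )
        _, ss_vec = _profile_t0_vectorised(
            arrays, spec, theta, config.V0, config.t0_bracket,
            config.coarse_step, config.fine_step,
        )
        return float(ss_vec.sum())

    def neg(theta: np.ndarray) -> float:
        ss = _ss(np.asarray(theta, dtype=float))
        if not np.isfinite(ss):
            return np.inf
        if df_adjusted:
            return 0.5 * nu * math.log(max(ss, floor_ss))
        ll, _ = _profiled_loglik(ss, n, config.eps_floor)
        return -ll

    return neg
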