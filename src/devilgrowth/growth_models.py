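"""Five classical tumour growth laws as ODEs and closed-form solutions.

Each law describes tumour volume V(t) (cm^3) over time t (days).  All
trajectories are anchored at a reference volume ``V0`` reached at a latent
per-tumour time ``t0``: V(t0) = V0.  The laws and their parameters:

=================  ==========================  ==========================================
law                dV/dt                       parameters
=================  ==========================  ==========================================
exponential        r V                         r: growth rate /day
logistic           r V (1 - V/K)               r: rate /day, K: carrying capacity cm^3
mendelsohn         r V^b                       r: rate /day, b: shape exponent (b != 1)
gompertz           r V exp(-rho (t - t0))      r: rate /day, rho: rate-decay /day
von_bertalanffy    alpha V^(2/3) - beta V      alpha: growth /day, beta: loss /day
=================  ==========================  ==========================================

The Gompertz right-hand side is time-inhomogeneous; its decay clock starts at
the anchor time t0, the only convention consistent with its closed form
V = V0 exp(r/rho (1 - exp(-rho (t - t0)))).

All solution functions are numpy-vectorised over time and return ``nan``
outside a law's valid time domain (e.g. the Mendelsohn finite-time
extinction/blow-up boundary) rather than raising, so that likelihood code can
treat invalid anchor placements as rejected (zero-likelihood) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "GrowthModelSpec",
    "AnchorConvention",
    "MODELS",
    "MODEL_NAMES",
    "get_model",
    "validate_theta",
    "model_rhs",
    "model_solution",
    "time_to_volume",
]

#: Reference volume (cm^3) at which each tumour's latent clock is anchored.
#: 0.125 cm^3 = 0.5 cm cubed, an estimate of the minimum visible tumour size.
#: The choice is cosmetic: it shifts every fitted anchor time by a constant
#: and leaves the maximised likelihood unchanged.
DEFAULT_V0 = 0.125

#: Floor on the profiled log-volume residual variance; guards noise-free data.
EPSILON_FLOOR = 1e-8


class DomainError(ValueError):
    """A volume/time outside the valid domain of a growth law."""


@dataclass(frozen=True)
class GrowthModelSpec:
    """One growth law: name, ordered parameter names and natural-scale bounds.

    ``k`` (the structural parameter count used by AICc) equals
    ``len(param_names)``; latent anchor times and the error variance are
    profiled nuisances and are not counted here.
    """

    name: str
    param_names: Tuple[str, ...]
    bounds: Tuple[Tuple[float, float], ...]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.param_names):
            raise ValueError("bounds/param_names length mismatch")
        for (lo, hi), p in zip(self.bounds, self.param_names):
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {p} must satisfy 0 < lo < hi")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class AnchorConvention:
    """The (V0, t0) anchor: V(t0) = V0 with t0 in days relative to a
    tumour's first observation (t0 may be negative)."""

    V0: float = DEFAULT_V0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise ValueError("V0 must be positive")


# Parameter bounds are implementation choices (the study reports fitted
# values only for r and K): rates bounded well away from 0 and absurdity,
# K spans sub-cm^3 to far beyond any observed devil tumour.
MODELS: Dict[str, GrowthModelSpec] = {
    "exponential": GrowthModelSpec("exponential", ("r",), ((1e-4, 1.0),)),
    "logistic": GrowthModelSpec("logistic", ("r", "K"), ((1e-4, 1.0), (1.0, 1e5))),
    "mendelsohn": GrowthModelSpec("mendelsohn", ("r", "b"), ((1e-4, 1.0), (0.05, 3.0))),
    "gompertz": GrowthModelSpec("gompertz", ("r", "rho"), ((1e-4, 1.0), (1e-5, 0.5))),
    "von_bertalanffy": GrowthModelSpec(
        "von_bertalanffy", ("alpha", "beta"), ((1e-4, 10.0), (1e-4, 1.0))
    ),
}

MODEL_NAMES = tuple(MODELS)

#: Mendelsohn b may not equal 1 (the law degenerates to exponential there);
#: validate_theta rejects a neighbourhood of this width around 1.
_MENDELSOHN_B_EXCLUSION = 1e-9


def get_model(name: str) -> GrowthModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown growth model {name!r}; choose from {', '.join(MODELS)}"
        ) from None


def validate_theta(spec: GrowthModelSpec, theta: Sequence[float]) -> np.ndarray:
    """Check length, positivity/bounds and the Mendelsohn b != 1 exclusion."""
    th = np.asarray(theta, dtype=float)
    if th.shape != (spec.k,):
        raise ValueError(
            f"{spec.name} expects {spec.k} parameters {spec.param_names}, got {th.shape}"
        )
    for val, pname, (lo, hi) in zip(th, spec.param_names, spec.bounds):
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"{spec.name} parameter {pname} must be positive, got {val}")
        if not (lo <= val <= hi):
            raise ValueError(
                f"{spec.name} parameter {pname}={val} outside bounds [{lo}, {hi}]"
            )
    if spec.name == "mendelsohn" and abs(th[1] - 1.0) < _MENDELSOHN_B_EXCLUSION:
        raise ValueError("mendelsohn exponent b = 1 degenerates to the exponential law")
    return th


# ---------------------------------------------------------------------------
# Right-hand sides dV/dt
# ---------------------------------------------------------------------------

def model_rhs(
    spec: GrowthModelSpec,
    theta: Sequence[float],
    V: float,
    dt_since_anchor: float = 0.0,
) -> float:
    """Instantaneous growth rate dV/dt (cm^3/day) of the named law.

    ``dt_since_anchor`` = t - t0 matters only for the time-inhomogeneous
    Gompertz law; the others ignore it.
    """
    th = validate_theta(spec, theta)
    V = float(V)
    if not V > 0:
        raise DomainError(f"volume must be positive, got {V}")
    if spec.name == "exponential":
        return th[0] * V
    if spec.name == "logistic":
        r, K = th
        return r * V * (1.0 - V / K)
    if spec.name == "mendelsohn":
        r, b = th
        return r * V**b
    if spec.name == "gompertz":
        r, rho = th
        return r * V * math.exp(-rho * dt_since_anchor)
    if spec.name == "von_bertalanffy":
        alpha, beta = th
        return alpha * V ** (2.0 / 3.0) - beta * V
    raise KeyError(spec.name)  # pragma: no cover


# ---------------------------------------------------------------------------
# Closed-form solutions V(t), vectorised over dt = t - t0
# ---------------------------------------------------------------------------

def _sol_exponential(th, V0, dt):
    return V0 * np.exp(th[0] * dt)


def _sol_logistic(th, V0, dt):
    r, K = th
    return K / (1.0 + (K / V0 - 1.0) * np.exp(-r * dt))


def _sol_mendelsohn(th, V0, dt):
    r, b = th
    base = (1.0 - b) * r * dt + V0 ** (1.0 - b)
    with np.errstate(invalid="ignore"):
        out = np.where(base > 0, base, np.nan) ** (1.0 / (1.0 - b))
    return out


def _sol_gompertz(th, V0, dt):
    r, rho = th
    return V0 * np.exp((r / rho) * (1.0 - np.exp(-rho * dt)))


def _sol_von_bertalanffy(th, V0, dt):
    alpha, beta = th
    A = alpha / beta  # cube root of the equilibrium volume
    cbrt = A - (A - V0 ** (1.0 / 3.0)) * np.exp(-beta * dt / 3.0)
    with np.errstate(invalid="ignore"):
        out = np.where(cbrt > 0, cbrt, np.nan) ** 3
    return out


_SOLUTIONS: Dict[str, Callable] = {
    "exponential": _sol_exponential,
    "logistic": _sol_logistic,
    "mendelsohn": _sol_mendelsohn,
    "gompertz": _sol_gompertz,
    "von_bertalanffy": _sol_von_bertalanffy,
}


def solution_curve(
    spec: GrowthModelSpec, theta: np.ndarray, V0: float, dt: np.ndarray
) -> np.ndarray:
    """Unchecked vectorised V(t0 + dt); invalid times map to nan.

    Fast path for likelihood code: ``theta`` must already be validated.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _SOLUTIONS[spec.name](theta, V0, dt)


def model_solution(
    spec: GrowthModelSpec,
    theta: Sequence[float],
    anchor: AnchorConvention,
    t,
):
    """Closed-form V(t) of the named law anchored at V(anchor.t0) = anchor.V0.

    Scalar t gives a scalar; array t gives an array.  Raises
    :class:`DomainError` for scalar t outside the valid domain (reporting the
    boundary time for the Mendelsohn blow-up/extinction case).
    """
    th = validate_theta(spec, theta)
    t_arr = np.asarray(t, dtype=float)
    dt = t_arr - anchor.t0
    out = solution_curve(spec, th, anchor.V0, dt)
    if np.ndim(t) == 0:
        out = float(out)
        if not np.isfinite(out):
            msg = f"{spec.name} solution undefined at t - t0 = {float(dt)}"
            if spec.name == "mendelsohn":
                r, b = th
                t_boundary = anchor.t0 - anchor.V0 ** (1.0 - b) / ((1.0 - b) * r)
                msg += f" (domain boundary at t = {t_boundary:.6g})"
            raise DomainError(msg)
    return out


# ---------------------------------------------------------------------------
# Inverse problem: time to reach a target volume
# ---------------------------------------------------------------------------

def time_to_volume(
    spec: GrowthModelSpec,
    theta: Sequence[float],
    anchor: AnchorConvention,
    V_target: float,
) -> float:
    """Days after t0 at which V(t) = V_target, by closed-form inversion.

    Raises :class:`DomainError` when the law cannot reach the target (e.g.
    V_target >= K for the logistic law, or beyond the Gompertz plateau).
    Negative return values are valid: targets below V0 are reached before t0.
    """
    th = validate_theta(spec, theta)
    V0 = anchor.V0
    Vt = float(V_target)
    if not Vt > 0:
        raise DomainError("target volume must be positive")
    if Vt == V0:
        return 0.0
    name = spec.name
    if name == "exponential":
        return math.log(Vt / V0) / th[0]
    if name == "logistic":
        r, K = th
        if Vt >= K or V0 >= K:
            raise DomainError(f"logistic volume must lie below K={K}, got {Vt}")
        return math.log((K / V0 - 1.0) / (K / Vt - 1.0)) / r
    if name == "mendelsohn":
        r, b = th
        return (Vt ** (1.0 - b) - V0 ** (1.0 - b)) / ((1.0 - b) * r)
    if name == "gompertz":
        r, rho = th
        arg = 1.0 - (rho / r) * math.log(Vt / V0)
        if arg <= 0:
            plateau = V0 * math.exp(r / rho)
            raise DomainError(
                f"gompertz target {Vt} at or above plateau {plateau:.6g}"
            )
        return -math.log(arg) / rho
    if name == "von_bertalanffy":
        alpha, beta = th
        A = alpha / beta
        num = A - Vt ** (1.0 / 3.0)
        den = A - V0 ** (1.0 / 3.0)
        if den == 0.0 or num / den <= 0:
            raise DomainError(
                f"von_bertalanffy target {Vt} not reachable from V0={V0} "
                f"(equilibrium {A**3:.6g})"
            )
        return -3.0 / beta * math.log(num / den)
    raise KeyError(name)  # pragma: no cover
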