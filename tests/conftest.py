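"""Shared fixtures: small deterministic cohorts built in memory."""

import numpy as np
import pytest

from devilgrowth import (
    AnchorConvention,
    FitConfig,
    GroupSettings,
    SyntheticCohortConfig,
    TumourSeries,
    get_model,
    model_solution,
    simulate_cohort,
)


def make_series(
    spec_name,
    theta,
    t0,
    times,
    tumour_id="t1",
    noise=None,
    V0=0.125,
    **covariates,
):
    """Noise-free (or additively log-perturbed) series on an exact growth
    curve anchored at (t0, V0).  ``noise`` is a vector of log-residuals."""
    spec = get_model(spec_name)
    times = np.asarray(times, dtype=float)
    V = model_solution(spec, theta, AnchorConvention(V0=V0, t0=t0), times)
    if noise is not None:
        V = V * np.exp(np.asarray(noise, dtype=float))
    return TumourSeries(tumour_id=tumour_id, host_id=tumour_id, t=times, V=V, **covariates)


@pytest.fixture
def exact_exponential_cohort():
    """5 tumours, 3 points each, exactly on exponential curves (r = 0.02)
    with different anchor times."""
    r = 0.02
    return [
        make_series("exponential", [r], t0, [0.0, 90.0, 180.0], tumour_id=f"t{i}")
        for i, t0 in enumerate([-300.0, -150.0, -50.0, 0.0, 40.0])
    ]


@pytest.fixture
def noisy_logistic_cohort():
    """Deterministic noisy logistic cohort at the default generator world."""
    cfg = SyntheticCohortConfig(
        n_tumours=30,
        seed=42,
        groups={"diploid": GroupSettings("logistic", (0.016, 364.0), 1.0)},
    )
    series_set, truth = simulate_cohort(cfg)
    return series_set, truth


@pytest.fixture
def quick_fit_config():
    """Reduced multistart for unit-test speed; fits here are well-behaved."""
    return FitConfig(multistart=4, seed=0)
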