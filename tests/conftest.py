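"""Shared fixtures: small simulated cohorts and their hierarchical fits.

The expensive MCMC fits are session-scoped and shared between the unit tests
and the acceptance tests; all randomness is seeded so the suite is
deterministic.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from affectrisk import CohortConfig, simulate_cohort
from affectrisk.inference import (
    AffectData,
    ChoiceData,
    build_affect_model,
    build_choice_model,
    fit_hierarchical,
)
from affectrisk.inference.sampler import SamplerConfig
from affectrisk.recovery import RecoveryConfig, run_recovery

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def clean_cohort(n_participants: int, seed: int, **kw) -> CohortConfig:
    """Cohort config without contaminant participants."""
    return CohortConfig(
        n_participants=n_participants,
        n_trials=kw.pop("n_trials", 50),
        n_same_response=0,
        n_slider_static=0,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_report():
    """Ten simulated cohorts (N=30, 50 trials) with group c below 2, refit."""
    return run_recovery(
        RecoveryConfig(n_datasets=10, n_participants=30, c_range=(0.5, 2.0), seed=42)
    )


@pytest.fixture(scope="session")
def modulated_fits():
    """Base and full choice fits on one cohort generated WITH arousal modulation."""
    cohort = simulate_cohort(clean_cohort(40, seed=21))
    data = ChoiceData.from_trials(cohort.trials)
    return {
        "cohort": cohort,
        "data": data,
        "base": fit_hierarchical(build_choice_model("base"), data, SamplerConfig.fast(seed=9)),
        "full": fit_hierarchical(build_choice_model("full"), data, SamplerConfig.fast(seed=9)),
    }


@pytest.fixture(scope="session")
def null_full_fit():
    """Full choice fit on a cohort generated with every modulation beta at 0."""
    import dataclasses

    cfg = clean_cohort(30, seed=31)
    cfg = dataclasses.replace(cfg, choice=cfg.choice.null_modulation())
    cohort = simulate_cohort(cfg)
    data = ChoiceData.from_trials(cohort.trials)
    return fit_hierarchical(build_choice_model("full"), data, SamplerConfig.fast(seed=13))


@pytest.fixture(scope="session")
def affect_fit():
    """Affect-model fit on a clean valence cohort (N=20)."""
    cohort = simulate_cohort(clean_cohort(20, seed=8))
    data = AffectData.from_trials(cohort.trials, "valence")
    model = build_affect_model()
    draws = fit_hierarchical(
        model, data, SamplerConfig(chains=2, iterations=600, warmup=300, seed=2)
    )
    return {"cohort": cohort, "data": data, "model": model, "draws": draws}
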