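import numpy as np
import pandas as pd
import pytest

from spatialfrailty import (
    Cohort,
    GeneratorConfig,
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    cohort_from_frame,
    generate_cohort,
    run_mcmc,
)
from spatialfrailty.cohort import COVARIATE_ORDER


def make_frame(times, statuses, blocks=None, **overrides):
    """Small cohort table with neutral covariates unless overridden."""
    n = len(times)
    base = {
        "time": times,
        "status": statuses,
        "ga_weeks": [34.0] * n,
        "b_weight": [2.0] * n,
        "platelet": [50.0] * n,
        "hemorrhage": [0] * n,
        "pt_aptt": [0] * n,
        "block": blocks if blocks is not None else ["A"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def tiny_cohort() -> Cohort:
    return cohort_from_frame(
        make_frame([10.0, 20.0, 30.0], [1, 0, 1], blocks=["A", "B", "A"])
    )


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    cohort, _ = generate_cohort(GeneratorConfig(seed=1))
    return cohort


@pytest.fixture(scope="session")
def fitted_weibull(default_cohort):
    """One fitted Weibull chain on the default synthetic cohort, shared."""
    return run_mcmc(
        default_cohort, "weibull", config=SamplerConfig(seed=3)
    )


def make_samples(beta_draws, frailty_draws=None, family="weibull",
                 baseline_draws=None, blocks=None):
    """Hand-built PosteriorSamples for summary-level tests."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    M = beta_draws.shape[0]
    if frailty_draws is None:
        frailty_draws = np.zeros((M, 2))
    frailty_draws = np.asarray(frailty_draws, dtype=float)
    G = frailty_draws.shape[1]
    if blocks is None:
        blocks = [f"B{i}" for i in range(G)]
    if baseline_draws is None:
        baseline_draws = np.zeros((M, 2))  # unconstrained: shape=scale=1
    return PosteriorSamples(
        family=family,
        covariate_names=COVARIATE_ORDER,
        blocks=list(blocks),
        baseline_param_names=("log_shape", "log_scale"),
        baseline_draws=np.asarray(baseline_draws, dtype=float),
        beta_draws=beta_draws,
        frailty_draws=frailty_draws,
        sigma2_draws=np.ones(M),
        pointwise_ll=np.zeros((M, 1)),
        acceptance_rate=0.25,
        block_acceptance={"regression": 0.25, "frailty": 0.25},
        config=SamplerConfig(n_burn=0, n_keep=M),
        priors=PriorSpec(),
    )
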