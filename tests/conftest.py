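import numpy as np
import pandas as pd
import pytest

from cmrctsim.cohort import CohortParams, RefusalSpec, generate_cohort
from cmrctsim.trial import simulate_trial


@pytest.fixture(scope="session")
def default_params() -> CohortParams:
    return CohortParams()


@pytest.fixture(scope="session")
def small_params() -> CohortParams:
    """A small trial (10 clusters of 40) for fast fitting tests."""
    return CohortParams(J=40, K=10)


def make_clustered_survival(
    seed: int = 0,
    K: int = 12,
    J: int = 40,
    beta: float = -0.5,
    sigma2_u: float = 0.25,
    sigma2_eps: float = 0.0,
    gamma: float = 1.0,
    scale: float = 10.0,
    horizon: float = 8.0,
    subject_level_x: bool = True,
) -> pd.DataFrame:
    """Generic clustered censored survival data for Cox fitting tests.

    Subject-level binary covariate by default (so the coefficient is
    identified within clusters), normal cluster random intercept on the
    log-hazard, administrative censoring at ``horizon``.
    """
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(K), J)
    u = rng.normal(0.0, np.sqrt(sigma2_u), K)[g]
    eps = rng.normal(0.0, np.sqrt(sigma2_eps), K * J)
    if subject_level_x:
        x = rng.integers(0, 2, K * J)
    else:
        x = (g % 2).astype(int)
    lp = beta * x + u + eps
    t = scale * np.exp(-lp / gamma) * (-np.log(rng.random(K * J))) ** (1.0 / gamma)
    y = np.minimum(t, horizon)
    d = (t <= horizon).astype(int)
    return pd.DataFrame({"cluster": g, "x": x, "y": y, "c": 1 - d})


@pytest.fixture(scope="session")
def clustered_data() -> pd.DataFrame:
    return make_clustered_survival(seed=42)


@pytest.fixture(scope="session")
def null_trial(small_params) -> pd.DataFrame:
    """One simulated trial with zero refusal (x == z everywhere)."""
    params = small_params.with_(T_max=10.0)  # longer follow-up -> enough events
    cohort = generate_cohort(params, RefusalSpec(), seed=7)
    return simulate_trial(cohort, params, seed=8)


@pytest.fixture(scope="session")
def refusal_trial() -> pd.DataFrame:
    """A trial with risk-correlated refusal and a reasonable event count."""
    params = CohortParams(J=80, K=15, T_max=10.0)
    spec = RefusalSpec(p=0.3, tier_p="high", sign_p="negative")
    cohort = generate_cohort(params, spec, seed=21)
    return simulate_trial(cohort, params, seed=22)
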