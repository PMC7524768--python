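import numpy as np
import pandas as pd
import pytest

from machtrust.influence import estimate_tournament
from machtrust.regression import CONTINUOUS_PREDICTORS, standardize
from machtrust.synthetic import SyntheticConfig, generate_tournament
from machtrust.types import PipelineConfig

#: planted regression coefficients used by the recovery checks
PLANTED_BETA = {
    "skill[high]": 0.82,
    "skill[low]": 0.90,
    "confirming": -0.05,
    "difficulty": 0.04,
    "distance": -0.037,
    "uncertainty": -0.03,
    "reputation": -0.02,
    "helpfulness": -0.05,
    "lifetime": 0.01,
}


def synthesize_table(beta, n=500, noise_sd=0.05, seed=0):
    """Covariate rows with the response linear in z-scored predictors."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "question_id": [f"q{i % 25}" for i in range(n)],
            "skill": rng.choice(["high", "low"], size=n),
            "confirming": rng.integers(0, 2, size=n).astype(float),
        }
    )
    for col in CONTINUOUS_PREDICTORS:
        df[col] = rng.normal(0, 1, n)
    work, _ = standardize(df)
    lin = np.where(df["skill"] == "high", beta["skill[high]"], beta["skill[low]"])
    for col in beta:
        if col not in ("skill[high]", "skill[low]"):
            lin = lin + beta[col] * work[col].to_numpy()
    df["alpha"] = lin + rng.normal(0, noise_sd, n)
    return df


@pytest.fixture(scope="session")
def small_tournament():
    """A compact constant-weight tournament shared across test modules."""
    cfg = SyntheticConfig(
        n_questions=10, alpha_star=0.5, n_independent_questions=20, seed=7
    )
    return generate_tournament(cfg)


@pytest.fixture(scope="session")
def small_estimates(small_tournament):
    t = small_tournament
    return estimate_tournament(
        t.questions, t.forecasts, t.machine_forecasts, PipelineConfig()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
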