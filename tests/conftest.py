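import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chronopls import FeatureMatrix, SyntheticTruth, TraitVector, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SMALL_BLOCKS = {"GMV": 8, "FA": 4, "FC": 6}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """n=200 cohort with two strong planted modes over 18 features."""
    truth = SyntheticTruth.for_latent_r(
        0.4,
        mode_strengths=(4.0, 3.0),
        trait_weights=(1.0, 0.6),
        sex_effect=(0.0, 0.8),
        age_slope=(0.02, -0.02),
        block_sizes=SMALL_BLOCKS,
        seed=42,
    )
    return generate_cohort(200, truth=truth)


@pytest.fixture
def random_xy(rng):
    x = rng.standard_normal((50, 20))
    y = rng.standard_normal(50)
    return x, y


def make_features(values, block="GMV", ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = ids if ids is not None else pd.Index(
        [f"s{i}" for i in range(n)], name="participant_id"
    )
    cols = [f"{block}_{j:03d}" for j in range(p)]
    return FeatureMatrix(pd.DataFrame(values, index=idx, columns=cols))


def make_trait(codes, ids=None):
    codes = np.asarray(codes, dtype=float)
    idx = ids if ids is not None else pd.Index(
        [f"s{i}" for i in range(len(codes))], name="participant_id"
    )
    return TraitVector(pd.Series(codes, index=idx, name="trait"))
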