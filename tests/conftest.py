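import numpy as np
import pandas as pd
import pytest

from ihc4pipe.synthetic_cohort import CohortConfig, HazardConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-sized cohort shared by read-only tests."""
    cfg = CohortConfig(n_patients=1200)
    return generate_cohort(cfg, HazardConfig(), seed=7)


def make_survival_frame(rng, n=200, beta=0.0, binary=True):
    """Minimal (time, event, x) frame under an exponential PH null/alternative."""
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(1.0, size=n) / np.exp(beta * x)
    c = rng.uniform(0.5, 2.5, size=n)
    return pd.DataFrame(
        {
            "time_years": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": x,
        }
    )
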