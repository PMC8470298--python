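import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_follows():
    """Two hand-built follows mixing control, impact and transition pairs."""
    from dolphinwatch.records import FocalFollow, Scan

    f1 = FocalFollow(
        "A",
        (
            Scan("A", 0, "REST", 0),
            Scan("A", 1, "REST", 0),
            Scan("A", 2, "SOC", 0),
            Scan("A", 3, "TRAV", 2, compliant=True, response="neutral"),
            Scan("A", 4, "TRAV", 2, compliant=False, response="avoidance"),
        ),
    )
    f2 = FocalFollow(
        "B",
        (
            Scan("B", 0, "MIL", 1, compliant=True, response="neutral"),
            Scan("B", 1, "MIL", 1, compliant=True, response="neutral"),
            Scan("B", 2, "DIV", 0),
        ),
    )
    return [f1, f2]


@pytest.fixture
def synth_config():
    from dolphinwatch.synth import SyntheticConfig

    return SyntheticConfig(seed=12345)


@pytest.fixture
def glmm_data():
    """Synthetic avoidance observations from a known logistic model.

    50 groups x 20 observations, logit = -1 + 0.6*vessels - 1.5*compliant,
    random-intercept SD 0.8.
    """
    import pandas as pd

    gen = np.random.default_rng(777)
    rows = []
    for g in range(50):
        b = gen.normal(0, 0.8)
        for _ in range(20):
            vessels = int(gen.integers(1, 9))
            compliant = int(gen.random() < 0.8)
            eta = -1.0 + 0.6 * vessels - 1.5 * compliant + b
            rows.append(
                {
                    "follow_id": f"G{g:02d}",
                    "avoided": int(gen.random() < 1 / (1 + np.exp(-eta))),
                    "n_vessels": vessels,
                    "compliant": compliant,
                    "group_size": int(gen.integers(20, 80)),
                    "cohesion": ["low", "intermediate", "high"][int(gen.integers(3))],
                    "behaviour": "REST",
                }
            )
    return pd.DataFrame(rows)


def pytest_configure(config):
    # follow-length warnings are routine in synthetic stress tests
    warnings.filterwarnings("ignore", message=".*outside the usual.*")
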