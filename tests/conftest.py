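import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import defnpipe as dp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_partition():
    """Two networks, A with 3 ROIs and B with 2: small enough to enumerate
    every edge by hand (3 within-A, 6 between, 1 within-B)."""
    return dp.gen_network_partition([3, 2], ["A", "B"])


@pytest.fixture(scope="session")
def desk_cohort():
    """One desk-scale healthy cohort shared by the slower stage-1 tests."""
    cfg = dp.desk_scale_config(seed=5)
    episodes, partition, truth = dp.gen_healthy_cohort(cfg)
    return cfg, episodes, partition, truth


@pytest.fixture(scope="session")
def desk_series(desk_cohort):
    cfg, episodes, partition, truth = desk_cohort
    series = [
        dp.sliding_window_fc(
            ep["ts"], dp.DfcConfig(), subject_id=ep["subject_id"],
            episode_id=ep["episode_id"], condition=ep["condition"],
        )
        for ep in episodes
    ]
    return series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
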