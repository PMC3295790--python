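import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Small but EB-viable study (>=100 ok probes per array)."""
    from methfid.synthetic import SimulationConfig

    return SimulationConfig(n_probes_per_category=60, seed=7)


@pytest.fixture(scope="session")
def small_probes(small_config):
    from methfid.synthetic import generate_probe_set

    return generate_probe_set(small_config)


@pytest.fixture()
def null_signal():
    """A pure-null normalized signal for direct EB/normalization tests."""
    rng = np.random.default_rng(11)
    n = 500
    s2 = np.full(n, 0.004)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:04d}" for i in range(n)],
            "M": rng.normal(0, np.sqrt(0.01 + s2)),
            "A": rng.uniform(9, 16, n),
            "s2_intra": s2,
            "flag": "ok",
        }
    )


def mixture_signal(pi1, tau0_2, tau1_2, n, seed, s2_value=0.004):
    """Draw a normalized signal directly from the EB generative model."""
    rng = np.random.default_rng(seed)
    s2 = np.full(n, s2_value)
    wide = rng.random(n) < pi1
    sd = np.sqrt(np.where(wide, tau1_2, tau0_2) + s2)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(n)],
            "M": rng.normal(0, 1, n) * sd,
            "A": rng.uniform(9, 16, n),
            "s2_intra": s2,
            "flag": "ok",
        }
    ), wide
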