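import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_table():
    """Tiny paired two-arm abundance table with hand-set counts."""
    from eubflow import AbundanceTable

    counts = pd.DataFrame(
        {
            "T_B_01": [10, 20, 30, 5, 100],
            "T_A_01": [12, 18, 33, 6, 95],
            "T_B_02": [11, 22, 28, 4, 110],
            "T_A_02": [9, 25, 31, 5, 105],
            "C_B_01": [10, 21, 29, 5, 99],
            "C_A_01": [10, 19, 32, 6, 101],
            "C_B_02": [12, 20, 30, 4, 98],
            "C_A_02": [11, 23, 27, 5, 104],
        },
        index=[f"genus{i}" for i in range(5)],
    )
    meta = pd.DataFrame(
        [(s, s.split("_")[0], s.split("_")[1], s.split("_")[0] + s.split("_")[2])
         for s in counts.columns],
        columns=["sample", "arm", "timepoint", "subject"],
    ).set_index("sample")
    return AbundanceTable(counts=counts, metadata=meta)


@pytest.fixture
def sim_config():
    from eubflow import SimConfig

    return SimConfig(arms=("T", "C"), eubiotic_effect={"T": 1.5, "C": 0.0},
                     n_genera=40, n_subjects_per_arm=6, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
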