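import numpy as np
import pandas as pd
import pytest

from anthrorisk import default_config, generate_cohort


@pytest.fixture(scope="session")
def cohort20k() -> pd.DataFrame:
    """The default stated-world cohort at full size (shared across tests)."""
    return generate_cohort(default_config(n=20000, seed=1))


@pytest.fixture(scope="session")
def cohort4k() -> pd.DataFrame:
    """A moderate cohort for fit tests where full size is unnecessary."""
    return generate_cohort(default_config(n=4000, seed=11))


@pytest.fixture()
def toy_cohort() -> pd.DataFrame:
    """Six handmade subjects covering both sexes and a spread of body sizes."""
    return pd.DataFrame(
        {
            "subject_id": [f"T{i}" for i in range(6)],
            "female": [0, 0, 0, 1, 1, 1],
            "race_black": [0, 1, 0, 0, 1, 0],
            "age_years": [25.0, 40.0, 60.0, 30.0, 50.0, 70.0],
            "height_cm": [176.0, 182.0, 169.0, 160.0, 155.0, 166.0],
            "weight_kg": [70.0, 95.0, 80.0, 55.0, 72.0, 64.0],
            "waist_cm": [84.0, 103.0, 95.0, 70.0, 90.0, 81.0],
            "hip_cm": [96.0, 108.0, 101.0, 92.0, 105.0, 98.0],
            "sample_weight": [1.0, 2.0, 1.0, 1.5, 1.0, 0.5],
            "followup_years": [20.0, 15.0, 8.0, 20.0, 12.0, 5.0],
            "died": [0, 1, 1, 0, 0, 1],
            "pregnant": [0, 0, 0, 0, 0, 0],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
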