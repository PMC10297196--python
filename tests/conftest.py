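import numpy as np
import pandas as pd
import pytest

from camvol.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 147-image / 208-nodule cohort at the frozen seed."""
    cfg = CohortConfig()
    truth, params = generate_cohort(cfg)
    return cfg, truth, params


@pytest.fixture()
def small_config():
    """A small cohort config for fast pipeline tests: 15 images, 22 nodules."""
    return CohortConfig(
        n_images_by_nodule_count={1: 10, 2: 3, 3: 2},
        n_patients=7,
        volume_mean_mm3=2000.0,
        volume_sd_mm3=2000.0,
        volume_min_mm3=110.0,
        volume_max_mm3=20000.0,
        grid_size=(256, 256),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230601)
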