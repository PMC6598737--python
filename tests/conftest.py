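import numpy as np
import pytest

from progmod.synthetic_cohort import default_two_group_config, generate_cohort


@pytest.fixture(scope="session")
def roi_cohort():
    """Two-group eight-ROI volume cohort with known orderings."""
    config = default_two_group_config(seed=7, n_controls=80, n_patients_per_group=80)
    table, truth = generate_cohort(config)
    return config, table, truth


@pytest.fixture(scope="session")
def cognitive_cohort():
    """Floored cognitive-score cohort (KDE mixture territory)."""
    config = default_two_group_config(seed=19, cognitive=True,
                                      n_controls=60, n_patients_per_group=80)
    table, truth = generate_cohort(config)
    return config, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
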