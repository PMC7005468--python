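import warnings

import numpy as np
import pytest

from pedmri.synthetic import (
    CohortConfig,
    default_class_profile,
    generate_subject,
    sample_feature_table,
)


@pytest.fixture(scope="session")
def profile():
    return default_class_profile()


@pytest.fixture(scope="session")
def small_config():
    """A small, fast phantom configuration (noiseless)."""
    return CohortConfig(
        n_per_class=(2, 2, 2),
        grid_shape=(12, 12, 10),
        voxel_size_mm=(3.0, 3.0, 3.0),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_subject(small_config, profile):
    """One noiseless ependymoma phantom (leaky tumour, known ground truth)."""
    rng = np.random.default_rng(11)
    return generate_subject(small_config, profile, "ependymoma", "sub-001", rng)


@pytest.fixture(scope="session")
def quantified(noiseless_subject):
    """The noiseless subject pushed through ADC + DSC quantification."""
    from pedmri.io import quantify_to_maps

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return quantify_to_maps(noiseless_subject)


@pytest.fixture(scope="session")
def feature_table():
    """A study-sized feature table drawn from the class profiles."""
    return sample_feature_table(n_per_class=(22, 17, 10), seed=42)
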