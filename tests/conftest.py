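import numpy as np
import pytest

import levylangevin as ll


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Three networks spanning the Gaussian-to-Levy spectrum."""
    return ll.CohortSpec(
        networks=[
            ll.NetworkTruth("heavy", ll.DriftModel(0.3, 1.0), ll.centered_noise(1.1, 0.0, 1.0)),
            ll.NetworkTruth("mid", ll.DriftModel(0.3, 0.0), ll.centered_noise(1.5, 0.0, 1.0)),
            ll.NetworkTruth("gauss", ll.DriftModel(0.3, -1.0), ll.centered_noise(2.0, 0.0, 1.0)),
        ],
        n_subjects=10,
        n_timepoints=850,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    return ll.generate_cohort(small_cohort_spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
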