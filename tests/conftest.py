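import numpy as np
import pytest
from hypothesis import settings

from ramanmargin.preprocess import fit_calibration
from ramanmargin.spectra import default_axis
from ramanmargin.synthetic import (
    CohortSpec,
    generate_polycarbonate,
    generate_reference_standard,
    make_class_profiles,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def profiles():
    return make_class_profiles()


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def standard(axis):
    return generate_reference_standard(axis, seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def calibration(axis):
    return fit_calibration(generate_polycarbonate(axis, seed=2))


@pytest.fixture(scope="session")
def small_clean_spec():
    """Small clean cohort (no planted failures) for fast end-to-end tests."""
    return CohortSpec(
        n_patients=10,
        measurements_per_patient=10,
        planted_qc_failures=0,
        planted_no_category=0,
        planted_label_mismatches=0,
        seed=3,
    )
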