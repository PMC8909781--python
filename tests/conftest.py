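import numpy as np
import pytest

from psmaquant import phantom, pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _single_sphere_spec(**overrides):
    defaults = dict(
        lesions=[
            phantom.PhantomLesionSpec(
                compartment="bone",
                center=(24, 24, 24),
                semi_axes=(10.0, 10.0, 10.0),
                peak_suv=9.0,
            )
        ],
        shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        noise_sd=0.0,
        psf_fwhm_mm=0.0,
        seed=7,
        patient_id="PX",
    )
    defaults.update(overrides)
    return phantom.PhantomSpec(**defaults)


@pytest.fixture
def sphere_spec():
    """A single noiseless, unblurred 10 mm sphere on a 2 mm isotropic grid."""
    return _single_sphere_spec()


@pytest.fixture
def make_spec():
    return _single_sphere_spec


@pytest.fixture(scope="session")
def noisy_cohort():
    return phantom.generate_cohort(n_patients=30, seed=1)


@pytest.fixture(scope="session")
def noisy_records(noisy_cohort):
    records, results = pipeline.analyze_cohort(noisy_cohort)
    return records, results


@pytest.fixture(scope="session")
def noiseless_cohort():
    return phantom.generate_cohort(n_patients=30, seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_cohort):
    records, results = pipeline.analyze_cohort(noiseless_cohort)
    return records, results
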