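import numpy as np
import pytest

from earnorms import build_manifest, default_config, generate_cohort


@pytest.fixture(scope="session")
def manifest():
    return build_manifest(seed=1)


@pytest.fixture(scope="session")
def calibrated_config():
    """The generator calibrated to the published normative descriptives
    (cached by the library; calibration simulates a few large cohorts)."""
    return default_config()


@pytest.fixture(scope="session")
def cohort_20k(calibrated_config):
    """One large calibrated cohort shared by the statistical checks."""
    return generate_cohort(calibrated_config, n=20_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
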