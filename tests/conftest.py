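import warnings

import numpy as np
import pytest

from perfml.cohort import (
    AcquisitionDesign,
    AifShapeParams,
    SignalModelParams,
    generate_cohort,
)

warnings.filterwarnings("ignore", message="test-set MBF variance")


@pytest.fixture(scope="session")
def default_design():
    return AcquisitionDesign()


@pytest.fixture(scope="session")
def small_design():
    """Two subjects, rest only, no exclusions: 48 records, fast to process."""
    return AcquisitionDesign(
        n_subjects=2, states=("rest",), excluded_sessions=(), artefact_prevalence=0.5
    )


@pytest.fixture(scope="session")
def noise_free_sig():
    return SignalModelParams(noise_sd=0.0, aif_noise_sd=0.0)


@pytest.fixture(scope="session")
def times60():
    return np.arange(60.0)


@pytest.fixture(scope="session")
def plain_aif_params():
    """Single-pass gamma-variate without recirculation, onset at 10 s."""
    return AifShapeParams(recirculation_fraction=0.0)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(AcquisitionDesign(), seed=11)
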