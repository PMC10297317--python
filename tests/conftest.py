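import numpy as np
import pytest

from tcdonn.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort (60 s recordings) shared by harness-level tests."""
    spec = SyntheticCohortSpec(duration_s=60.0, seed=7)
    manifest, envelopes = generate_cohort(spec)
    return spec, manifest, envelopes
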