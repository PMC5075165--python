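import numpy as np
import pytest
from hypothesis import settings

from nodax.simulate import GeneratorConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    """The default cohort written to a directory of CSV tables."""
    from nodax.io import write_cohort

    path = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
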