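import numpy as np
import pytest
from hypothesis import settings

from rnafep.cycle import RestraintScheme
from rnafep.synthetic import StudySpec, gen_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A reduced-size healthy study shared by several suites."""
    spec = StudySpec(
        ligands=(("ligA", -8.0), ("ligB", -6.0), ("ligC", -4.0)),
        n_replicates=3,
        n_samples=400,
        n_windows_complex=10,
        n_windows_bulk=8,
        seed=11,
    )
    return gen_study(spec)


@pytest.fixture
def scheme():
    return RestraintScheme()
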