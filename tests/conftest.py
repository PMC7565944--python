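import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from glutsite.pssm import Profile
from glutsite.synthetic import SyntheticSpec, generate_dataset
from glutsite.windows import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_protein():
    # K at 2 (annotated), 7, 12
    return ProteinRecord(
        id="P1",
        sequence="AKCDEFKGHILKMNP",
        positive_positions=frozenset({2}),
    )


@pytest.fixture
def random_profile(rng):
    return Profile(source_id="rand", scores=rng.normal(0, 3, size=(21, 20)))


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """A clearly separable synthetic dataset shared by the slower tests."""
    spec = SyntheticSpec(seed=7, n_proteins=30, site_rate=0.4, effect_size=3.0)
    return generate_dataset(spec, n_per_class=60)
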