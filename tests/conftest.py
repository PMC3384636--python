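import numpy as np
import pytest

from episcan import FixtureSpec, Fragment, gen_fragment_dataset
from episcan.fixtures import make_scale


def make_fragment(peptide="ACDEFGHIKLMNPQRSTVWY",
                  ss="H" * 20, rsa=None, conservation=None,
                  threshold=0.25) -> Fragment:
    """Hand-build an annotated 20-mer with simple default channels."""
    rsa = np.full(20, 0.5) if rsa is None else np.asarray(rsa, float)
    con = (np.zeros(20) if conservation is None
           else np.asarray(conservation, float))
    return Fragment(peptide=peptide, ss=ss, rsa=rsa,
                    exposure=rsa >= threshold, conservation=con)


def random_fragment(rng) -> Fragment:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    pep = "".join(rng.choice(list(aas), 20))
    ss = "".join(rng.choice(list("HEC"), 20))
    rsa = rng.random(20)
    return Fragment(peptide=pep, ss=ss, rsa=rsa, exposure=rsa >= 0.25,
                    conservation=rng.normal(1.0, 0.5, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(20123)


@pytest.fixture(scope="session")
def toy_scale():
    return make_scale(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def small_fixture():
    """Small strong-signal fragment fixture for unit-level tests."""
    return gen_fragment_dataset(FixtureSpec(seed=11, n_epitope=40,
                                            n_non_epitope=40))
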