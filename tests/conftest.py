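import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epidesign as ed

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sak_peptide() -> str:
    return ed.SAKSTAR_71_87


@pytest.fixture(scope="session")
def blosum_sets(sak_peptide):
    """Allowed map + flag table for the packaged peptide under the default rule."""
    return ed.blosum_allowed(sak_peptide, max_diff=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_random_matrix(rng, window=9, alphabet=ed.AMINO_ACIDS, sd=1.0, allele="SYN*0000"):
    w = np.round(rng.normal(0, sd, size=(window, len(alphabet))), 1)
    return ed.PocketProfileMatrix(allele, w, alphabet=alphabet, window=window)
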