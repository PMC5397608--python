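import warnings

import pytest
from hypothesis import settings

from solubis.fixtures import make_toy_fv, make_toy_structure

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_cdr_fixture():
    """Toy Fv, 6-residue APR planted inside CDR-L1 (seed 1)."""
    return make_toy_fv(1, apr_in_cdr=True)


@pytest.fixture(scope="session")
def toy_fr_fixture():
    """Toy Fv, 6-residue APR planted in FR3 of the light chain (seed 1)."""
    return make_toy_fv(1, apr_in_cdr=False)


@pytest.fixture(scope="session")
def toy_structures(toy_cdr_fixture):
    """Buried/exposed structure pair for the CDR fixture: identical sequences."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for burial in ("buried", "exposed"):
            out[burial] = make_toy_structure(toy_cdr_fixture, burial)
    return out
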