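import io

import pytest

from commchem import make_refdb, make_rdp_fixture, read_rdp_hierarchy


@pytest.fixture(scope="session")
def toy_refdb():
    return make_refdb(seed=11, n_phyla=3, genera_per_phylum=4)


@pytest.fixture(scope="session")
def bundle(toy_refdb):
    """Fixture with unmapped and filtered reads, ground truth by construction."""
    return make_rdp_fixture(
        toy_refdb, n_samples=4, seed=7, unmapped_fraction=0.05, filtered_fraction=0.1
    )


@pytest.fixture(scope="session")
def matched_bundle(toy_refdb):
    """Fixture whose classification taxonomy equals the reference taxonomy."""
    return make_rdp_fixture(toy_refdb, n_samples=4, seed=3)


@pytest.fixture()
def classification(bundle):
    return read_rdp_hierarchy(io.StringIO(bundle.rdp_text))
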