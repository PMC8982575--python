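import pytest

from mirab import cloning, oligo_design


@pytest.fixture(scope="session")
def bundled_pairs():
    """The bundled ground-truth oligo table (one row per published shRNAmir)."""
    return oligo_design.load_bundled_oligos()


@pytest.fixture(scope="session")
def bundled_cassettes(bundled_pairs):
    return [oligo_design.parse_oligos(p) for p in bundled_pairs]


@pytest.fixture(scope="session")
def pair_by_name(bundled_pairs):
    return {p.name: p for p in bundled_pairs}


@pytest.fixture(scope="session")
def mock_vector():
    vec, ann = cloning.make_mock_vector(seed=11)
    return vec, ann
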