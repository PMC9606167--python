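import numpy as np
import pytest

from markerscan import (
    CommunitySpec,
    KNOWN_PAIRS,
    MarkerTemplate,
    SequenceCollection,
    SequenceRecord,
    generate_community,
    mock_community_8,
)


def make_alignment(*seqs: str, aligned: bool = True) -> SequenceCollection:
    records = [SequenceRecord(id=f"s{i + 1}", seq=s) for i, s in enumerate(seqs)]
    return SequenceCollection(records=records, aligned=aligned)


@pytest.fixture(scope="session")
def mock8():
    return mock_community_8(seed=0)


@pytest.fixture(scope="session")
def small_community():
    """6 species x 3 strains, last 2 species with broken primer sites."""
    pair = KNOWN_PAIRS["gyrA3"]
    spec = CommunitySpec(
        markers=[MarkerTemplate(name="gyrA", length=800, pair=pair,
                                fwd_pos=100, rev_pos=560)],
        n_species=6,
        strains_per_species=3,
        n_incompatible_species=2,
        seed=7,
    )
    return generate_community(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
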