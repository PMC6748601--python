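import pytest

from abmatch import (
    Chain,
    ImgtPosition,
    NumberedChain,
    StudyMetadata,
    read_table1_fixture,
)
from abmatch.simulate import SyntheticConfig, generate_repertoire


def make_chain(seq, record_id="q", chain=Chain.HEAVY, start=1, meta=None):
    """Number a plain string sequentially from `start` (test helper)."""
    residues = {ImgtPosition(start + i): aa for i, aa in enumerate(seq)}
    return NumberedChain(record_id=record_id, chain=chain, residues=residues, meta=meta)


@pytest.fixture(scope="session")
def fixture_rows():
    return read_table1_fixture()


@pytest.fixture(scope="session")
def small_repertoire():
    """500 seeded heavy-chain records used by several search tests."""
    cfg = SyntheticConfig(n_records=500, seed=11)
    return [g.numbered for g in generate_repertoire(cfg)]


@pytest.fixture
def study_meta():
    return StudyMetadata(study_id="S1", species="human", chain=Chain.HEAVY)
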