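import pytest

from comorbidnet.io_model import DisorderGeneTable
from comorbidnet.synthetic_data import SyntheticScenario


@pytest.fixture
def toy_tables() -> DisorderGeneTable:
    """Four disorders with a focal ('ASD') sharing genes with two of them."""
    return DisorderGeneTable(
        {
            "ASD": frozenset({"A", "B", "C"}),
            "D1": frozenset({"B", "X"}),
            "D2": frozenset({"C", "X", "Y"}),
            "D3": frozenset({"Z"}),
        },
        focal="ASD",
    )


@pytest.fixture
def small_scenario() -> SyntheticScenario:
    """Small but fully structured scenario for fast recovery tests."""
    return SyntheticScenario(
        n_groups=3,
        disorders_per_group=6,
        core_size=40,
        private_size=8,
        share_prob=0.9,
        n_planted_candidates=10,
        n_null_candidates=10,
        n_case=10,
        n_control=8,
        seed=11,
    )
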