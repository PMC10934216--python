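import pytest

from ssrscape import example_taxonomy, fixture_small, simulate, standard_plan
from ssrscape.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_sim():
    """Deterministic 5-sample, 10-locus miniature dataset."""
    return fixture_small()


@pytest.fixture(scope="session")
def recovery_sim():
    """24-sample, 55-locus dataset with planted SSRs of every category,
    compound groups, edge truncations and an exon/flank split."""
    taxonomy = example_taxonomy(24)
    planted = standard_plan(taxonomy, 55, seed=5, with_exons=True)
    config = SimulationConfig(
        taxonomy=taxonomy, n_loci=55, seed=5, planted=planted, with_exons=True
    )
    return simulate(config)
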