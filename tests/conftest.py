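import pytest

from chromoforge import (
    DesignRuleSet, generate_toy_genome, partition_chunks, run_design,
)

TELOMERE_SEED = "ACGGTTTACCCTGTG" * 4


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(seed=42)


@pytest.fixture(scope="session")
def default_rules():
    return DesignRuleSet(telomere_seed=TELOMERE_SEED)


@pytest.fixture(scope="session")
def design_bundle(toy_genome, default_rules):
    """(designed genome, edit log, report) for the seed-42 toy chromosome."""
    return run_design(toy_genome, default_rules)


@pytest.fixture(scope="session")
def chunk_bundle(design_bundle):
    designed, _, _ = design_bundle
    chunks, genome = partition_chunks(designed)
    return chunks, genome
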