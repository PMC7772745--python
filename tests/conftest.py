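import pytest

from qtlannot.fixtures import (
    FixtureSpec,
    build_databases,
    simulate_records,
    toy_worked_examples,
)


@pytest.fixture(scope="session")
def toy():
    """Paths to the bundled micro-fixtures."""
    return toy_worked_examples()


@pytest.fixture
def small_dataset():
    """One deterministic in-memory dataset: candidates + gene/QTL databases."""
    spec = FixtureSpec(seed=7)
    candidates, genes, qtls = simulate_records(spec)
    gene_db, qtl_db = build_databases(genes, qtls)
    return spec, candidates, gene_db, qtl_db
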