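import pytest

from deapr import (
    FixtureSpec,
    generate,
    select_de_genes,
    sets_by_label,
)

FIXTURE_SEED = 1234


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic fixture: six sets x three replicates, all planted
    categories at their default counts, noise bound 1.3, fold change 4."""
    return generate(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def sets(bundle):
    return sets_by_label(bundle.sample_sets)


@pytest.fixture(scope="session")
def comp1(bundle, sets):
    """Mutant A vs no-mutant control (ref B11_0, test THP1_0)."""
    return select_de_genes(bundle.matrix, bundle.annotation, sets["B11_0"], sets["THP1_0"])


@pytest.fixture(scope="session")
def comp2(bundle, sets):
    """Mutant B vs no-mutant control (ref B11_0, test B11_1)."""
    return select_de_genes(bundle.matrix, bundle.annotation, sets["B11_0"], sets["B11_1"])


@pytest.fixture(scope="session")
def comp7(bundle, sets):
    """Dose escalation within cell line B (ref B11_1, test B11_10)."""
    return select_de_genes(bundle.matrix, bundle.annotation, sets["B11_1"], sets["B11_10"])
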