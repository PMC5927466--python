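import pytest

from triomic import (
    DifferentialExpressionModel,
    MetaboliteEnrichmentModel,
    MethylationModel,
    generate_expression,
    generate_metabolomics,
    generate_methylation,
)


@pytest.fixture(scope="session")
def expr_study():
    """Default planted expression study (500 genes, 20% planted)."""
    return generate_expression(seed=1)


@pytest.fixture(scope="session")
def expr_results(expr_study):
    return DifferentialExpressionModel.from_study(expr_study).fit()


@pytest.fixture(scope="session")
def metab_study():
    return generate_metabolomics(seed=1)


@pytest.fixture(scope="session")
def metab_results(metab_study):
    return MetaboliteEnrichmentModel.from_study(metab_study).fit()


@pytest.fixture(scope="session")
def meth_study():
    """Planted methylation study with the day-6 shift layout."""
    return generate_methylation(seed=1, effect_days=[6])


@pytest.fixture(scope="session")
def meth_results(meth_study):
    return MethylationModel.from_study(meth_study).fit()
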