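import pytest

from kgchain.chain_model import ReasoningRuleChain, rrc_to_pcs
from kgchain.rdf_model import fixture_g0

HERB_GENE_PROPERTIES = (
    "treatment",
    "possibleDrug",
    "hasTarget",
    "hasAccession",
    "classifiedWith",
    "symbol",
)
HERB_GENE_CLASSES = (
    "Herb", "Disease", "Drug", "Target", "Protein", "EntrezID", "Gene",
)


@pytest.fixture
def g0():
    """The eight-triple herb-to-gene worked-example graph."""
    return fixture_g0()


@pytest.fixture
def herb_gene_rrc():
    """The six-rule herb-to-gene reasoning chain."""
    return ReasoningRuleChain.from_properties(HERB_GENE_PROPERTIES, HERB_GENE_CLASSES)


@pytest.fixture
def pcs0(herb_gene_rrc):
    """Initial PCS of the herb-to-gene chain: six single-property OPCs."""
    return rrc_to_pcs(herb_gene_rrc)


@pytest.fixture
def chains_yaml(tmp_path):
    """A chain-config file with the herb→gene and herb→ingredient chains."""
    path = tmp_path / "chains.yaml"
    path.write_text(
        "chains:\n"
        "  - id: herb_gene\n"
        "    source_class: Herb\n"
        "    sink_class: Gene\n"
        "    properties: [treatment, possibleDrug, hasTarget, hasAccession, classifiedWith, symbol]\n"
        "  - id: herb_ingredient\n"
        "    source_class: Herb\n"
        "    sink_class: Ingredient\n"
        "    properties: [treatment, possibleDrug, hasIngredient]\n"
    )
    return path
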