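import numpy as np
import pytest

from bioevent.standoff import parse_standoff
from bioevent.synthetic import GeneratorConfig, generate_corpus

# The running example used throughout: a sentence with a simple
# Gene_expression event nested as the Cause of a Positive_regulation event.
NESTED_TXT = "Bmi-1 over-expression is sufficient to promote tumorigenesis"
NESTED_A1 = (
    "T1\tGene_or_gene_product 0 5\tBmi-1\n"
    "T4\tPathological_formation 47 60\ttumorigenesis\n"
)
NESTED_A2 = (
    "T2\tGene_expression 6 21\tover-expression\n"
    "T3\tPositive_regulation 39 46\tpromote\n"
    "E1\tGene_expression:T2 Theme:T1\n"
    "E2\tPositive_regulation:T3 Theme:T4 Cause:E1\n"
)


@pytest.fixture
def nested_doc():
    """Document with one simple event nested under a regulation event."""
    return parse_standoff(NESTED_TXT, NESTED_A1, NESTED_A2, doc_id="nested")


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-sentence synthetic corpus shared by read-only tests."""
    return generate_corpus(GeneratorConfig(n_sentences=40, seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
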