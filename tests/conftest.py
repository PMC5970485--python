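import pytest

from scboolnet import (
    Cell,
    ClassSpec,
    ExpressionDataset,
    GeneParameters,
    GeneSet,
    build_state_graph,
    combine_rules,
    state_from_string,
    synthesize_all,
)

TOY_STATES = ("100", "110", "111", "011")


def make_toy_dataset() -> ExpressionDataset:
    """4 observed states over genes A, B, C forming the chain
    100 - 110 - 111 - 011, with 100 in the early class and 011 in the
    late class."""
    genes = GeneSet(["A", "B", "C"])
    labels = ["E3", "mid", "mid", "E7"]
    cells = [
        Cell(cell_id=str(i), class_label=lbl, state=state_from_string(s))
        for i, (s, lbl) in enumerate(zip(TOY_STATES, labels))
    ]
    return ExpressionDataset(genes=genes, cells=cells)


def make_toy_params() -> dict:
    return {
        "A": GeneParameters("A", 1, 1, 100.0),
        "B": GeneParameters("B", 1, 0, 50.0),
        "C": GeneParameters("C", 1, 0, 100.0),
    }


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()


@pytest.fixture
def toy_spec():
    return ClassSpec(initial_classes={"E3"}, target_classes={"E7"})


@pytest.fixture
def toy_graph(toy_dataset, toy_spec):
    return build_state_graph(toy_dataset, toy_spec)


@pytest.fixture
def toy_params():
    return make_toy_params()


@pytest.fixture
def toy_ruleset(toy_graph, toy_params):
    g, initial, final = toy_graph
    return synthesize_all(g, initial, final, toy_params)


@pytest.fixture
def toy_model(toy_ruleset):
    return combine_rules(toy_ruleset)
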