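import numpy as np
import pandas as pd
import pytest

from evodet import FeatureTable, SyntheticSpec, generate_synthetic_study


def make_table(values: dict, groups: dict, kinds: dict, responses: dict, genes=None):
    n = len(next(iter(values.values())))
    idx = pd.Index(genes if genes is not None else [f"g{i}" for i in range(n)], name="gene")
    return FeatureTable(
        pd.DataFrame(values, index=idx),
        groups,
        kinds,
        pd.DataFrame(responses, index=idx),
    )


@pytest.fixture
def simple_table():
    """3 genes x 2 continuous predictors in 2 groups, one response."""
    return make_table(
        {"expr": [1.0, 2.0, 3.0], "length": [10.0, 20.0, 30.0]},
        {"expr": "expression", "length": "size"},
        {"expr": "continuous", "length": "continuous"},
        {"dN": [0.1, 0.2, 0.3]},
    )


SMALL_SPEC = SyntheticSpec(
    n_genes=400,
    n_expression=12,
    n_size=6,
    n_go_component=15,
    n_go_process=10,
    n_go_function=8,
    n_informative_expression=4,
    n_informative_size=2,
)


@pytest.fixture(scope="session")
def small_study():
    """A toy-scale synthetic study shared by pipeline-level tests."""
    return generate_synthetic_study(SMALL_SPEC, seed=42)


@pytest.fixture(scope="session")
def small_study_networks(small_study, tmp_path_factory):
    from evodet import load_string_edges

    d = tmp_path_factory.mktemp("study")
    paths = small_study.write(d)
    functional = load_string_edges(paths["functional"], 0.400, "4896.")
    physical = load_string_edges(paths["physical"], 0.400, "4896.")
    return functional, physical


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
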