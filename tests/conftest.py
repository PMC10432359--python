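import numpy as np
import pytest

from autocdrp.space import ComponentDef, SearchSpace, default_space
from autocdrp.synthetic import SyntheticDatasetSpec, make_dataset


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture(scope="session")
def mini_space():
    """Enumerable space (256 architectures) with the default component names,
    so the curated edge scheme and the candidate-model builder both apply."""
    return SearchSpace(
        components=(
            ComponentDef("aggregation", ("add", "mean"), "per_layer"),
            ComponentDef("convolution", ("GCNConv", "GINConv"), "per_layer"),
            ComponentDef("dropout", ("False",), "per_layer"),
            ComponentDef("activation", ("relu", "Sigmoid"), "per_layer"),
            ComponentDef("normalizer", ("none",), "per_layer"),
            ComponentDef("hidden", ("16",), "per_layer"),
            ComponentDef("multi-head", ("1",), "per_layer"),
            ComponentDef("learning-rate", ("1e-3", "1e-2"), "global"),
            ComponentDef("weight-regulation", ("1e-4",), "global"),
            ComponentDef("optimizer", ("Adam",), "global"),
            ComponentDef("loss-criterion", ("CrossEntropyLoss",), "global"),
            ComponentDef("pooling", ("global_add_pool", "global_max_pool"), "global"),
        ),
        num_layers=2,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """10 drugs x 30 cells, fully observed, with planted signal."""
    return make_dataset(
        SyntheticDatasetSpec(n_drugs=10, n_cells=30, density=1.0, seed=4)
    )


def random_small_space(rng: np.random.Generator) -> SearchSpace:
    """A random small space for property tests."""
    n_comp = int(rng.integers(2, 5))
    comps = []
    for i in range(n_comp):
        n_opts = int(rng.integers(2, 5))
        scope = "per_layer" if rng.random() < 0.6 else "global"
        comps.append(
            ComponentDef(f"c{i}", tuple(f"o{i}_{j}" for j in range(n_opts)), scope)
        )
    if not any(c.scope == "per_layer" for c in comps):
        comps[0] = ComponentDef(comps[0].name, comps[0].options, "per_layer")
    return SearchSpace(tuple(comps), num_layers=int(rng.integers(1, 3)))
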