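import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from isolocal.simulate import SimConfig, simulate_yule_tree
from isolocal.traits import TraitTypeSpec
from isolocal.trees import PhyloTree

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def abc_tree() -> PhyloTree:
    """The worked three-tip example: ((A:1,B:1):1,C:2);"""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def xyz_traits() -> tuple[pd.DataFrame, TraitTypeSpec]:
    """Three species, one quantitative + one nominal trait, hand-checkable
    Gower distances 0.5 / 0.5 / 1.0."""
    table = pd.DataFrame(
        {"mass": [1.0, 3.0, 3.0], "habitat": ["forest", "forest", "grass"]},
        index=["X", "Y", "Z"],
    )
    spec = TraitTypeSpec(
        {"mass": "quantitative", "habitat": "nominal"}, {"mass": False}
    )
    return table, spec


def random_tree(seed: int, n_min: int = 2, n_max: int = 8) -> PhyloTree:
    """A small random Yule tree with randomised (non-ultrametric) edge
    lengths, some of them zero."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_yule_tree(SimConfig(n_species=max(n, 2)), rng)
    for node in tree.preorder():
        u = rng.random()
        node.length = 0.0 if u < 0.1 else float(rng.exponential(1.0))
    return tree
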