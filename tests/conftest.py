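import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from symscreen.synthetic_data import SimulationConfig, simulate_tree
from symscreen.io_formats import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20180717)


@pytest.fixture
def quartet():
    """Rooted 4-taxon tree ((A,B),(C,D)) with unit-ish branch lengths."""
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.08);")


@pytest.fixture
def small_config():
    """Six-taxon setting used for quick simulation-backed tests."""
    return SimulationConfig(seed=11, n_taxa=6, focal_clade_size=2, n_codons=120)


@pytest.fixture
def small_tree(small_config):
    return simulate_tree(small_config)


def random_binary_tree(labels, rng, mean_length=0.2):
    """Uniform random rooted binary topology over the given tip labels."""
    from symscreen.tree_ops import Node, Phylogeny

    lineages = [Node(label=l, length=float(rng.exponential(mean_length))) for l in labels]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node(length=float(rng.exponential(mean_length)))
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j] = parent
        lineages.pop(i)
    root = lineages[0]
    root.length = 0.0
    return Phylogeny(root)
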