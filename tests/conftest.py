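import numpy as np
import pytest
from hypothesis import settings

import divconflict as dc

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> dc.Tree:
    """Random binary topology with random positive branch lengths."""
    nodes = [dc.Node(label=f"t{i + 1}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dc.Node(length=float(rng.uniform(0.1, 2.0)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return dc.Tree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)


@pytest.fixture(scope="session")
def balanced_quartet():
    """((A,B),(C,D)) with internal node ages 1 (both cherries) and root 2."""
    return dc.compute_node_ages(
        dc.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))


def cherry_gene_tree(pairing: str) -> dc.Tree:
    """4-taxon gene trees displaying a chosen split."""
    topologies = {
        "AB|CD": "((A:1,B:1):1,(C:1,D:1):1);",
        "AC|BD": "((A:1,C:1):1,(B:1,D:1):1);",
        "AD|BC": "((A:1,D:1):1,(B:1,C:1):1);",
    }
    return dc.parse_newick(topologies[pairing])
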