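import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pmmtree.data import MISSING, CharacterMatrix, PMMParams, SiteAlphabet
from pmmtree.tree import LineageTree, random_binary_tree


@pytest.fixture
def alpha1():
    """Single-outcome site."""
    return SiteAlphabet(0, {1: 1.0})


@pytest.fixture
def alpha2():
    return SiteAlphabet(0, {1: 0.5, 2: 0.5})


@pytest.fixture
def alpha3():
    return SiteAlphabet(0, {1: 0.6, 2: 0.3, 3: 0.1})


@pytest.fixture
def cherry_tree():
    """((a,b)) with unit deltas."""
    t = LineageTree.from_newick("((a:1,b:1)x:1)root;")
    t.set_deltas({"a": 0.5, "b": 0.7, "x": 0.3})
    return t


@pytest.fixture
def quartet_tree():
    t = LineageTree.from_newick("(((a:1,b:1)u:1,(c:1,d:1)v:1)x:1)root;")
    t.set_deltas({"a": 0.4, "b": 0.6, "u": 0.3, "c": 0.5, "d": 0.2, "v": 0.7,
                  "x": 0.25})
    return t


def random_instance(rng, n_leaves=4, K=2, M=2, p_missing=0.25, nu=0.1, phi=0.15):
    """Random small tree + matrix + params for oracle comparisons."""
    names = [f"c{i}" for i in range(n_leaves)]
    tree = random_binary_tree(names, rng)
    delta = {}
    for node in tree.postorder():
        if node.parent is not None:
            delta[node.name] = float(rng.uniform(0.05, 1.2))
    tree.set_deltas(delta)
    alphabets = []
    cols = {}
    for k in range(K):
        q = rng.dirichlet(np.ones(M))
        alphabets.append(SiteAlphabet(k, {m + 1: float(p) for m, p in enumerate(q)},
                                      name=f"s{k}"))
        col = []
        for _ in range(n_leaves):
            if rng.random() < p_missing:
                col.append(MISSING)
            else:
                col.append(int(rng.integers(0, M + 1)))
        cols[f"s{k}"] = col
    matrix = CharacterMatrix(pd.DataFrame(cols, index=names), alphabets)
    params = PMMParams(delta=delta, nu=nu, phi=phi)
    return tree, matrix, params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
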