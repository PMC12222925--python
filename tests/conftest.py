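import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from shiftorder import synth, trees


@pytest.fixture
def cherry():
    return trees.parse_newick("(A:1,B:1);")


@pytest.fixture
def balanced4():
    return trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_yule(n, seed, birth=1.0):
    return synth.simulate_bd_tree(n, birth, 0.0, seed)


@pytest.fixture
def yule20():
    return random_yule(20, 42)


# -- brute-force oracles shared by the Mk tests ----------------------------

def brute_force_loglik(tree, tip_states, Q, prior):
    """Sum the joint likelihood over every internal-state assignment."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.blen]
    internals = list(range(tree.n_tips, tree.n_nodes))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for i in range(tree.n_tips):
            st[i] = tip_states[i]
        like = prior[st[tree.root]]
        for v in range(tree.n_nodes - 1):
            like *= P[v][st[tree.parent[v]], st[v]]
        total += like
    return np.log(total)


def brute_force_marginals(tree, tip_states, Q, prior):
    """Exact node posteriors by enumeration over internal assignments."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.blen]
    internals = list(range(tree.n_tips, tree.n_nodes))
    post = np.zeros((tree.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for i in range(tree.n_tips):
            st[i] = tip_states[i]
        like = prior[st[tree.root]]
        for v in range(tree.n_nodes - 1):
            like *= P[v][st[tree.parent[v]], st[v]]
        for v, s in st.items():
            post[v, s] += like
    return post / post.sum(axis=1, keepdims=True)
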