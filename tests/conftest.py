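"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from defenseflux import simulate
from defenseflux.gainloss import transition_matrix
from defenseflux.tree import PhyloTree, read_newick


@pytest.fixture()
def cherry() -> PhyloTree:
    return read_newick("(A:1.0,B:2.0);")


@pytest.fixture()
def three_tip() -> PhyloTree:
    return read_newick("((A:1,B:1):0.5,C:2);")


@pytest.fixture(scope="session")
def tree100() -> PhyloTree:
    """A 100-tip clocklike tree shared by slower statistical tests."""
    return simulate.simulate_tree(100, seed=2024)


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Yule topology with independently redrawn branch lengths."""
    tree = simulate.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    tree.lengths[1:] = rng.uniform(0.02, 2.0, tree.n_nodes - 1)
    return tree


def enumeration_likelihood_and_marginals(
    tree: PhyloTree, tipstates: np.ndarray, gain: float, loss: float, prior1: float
):
    """Brute-force trait likelihood and node marginals by summing over every
    internal-state assignment. Independent of the pruning implementation."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    kernels = {v: transition_matrix(gain, loss, tree.lengths[v]) for v in range(1, tree.n_nodes)}
    prior = [1.0 - prior1, prior1]
    fixed = {int(t): int(s) for t, s in zip(tree.tip_ids, tipstates)}
    total = 0.0
    acc = {v: np.zeros(2) for v in internal}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(fixed)
        st.update(zip(internal, assign))
        p = prior[st[0]]
        for v in range(1, tree.n_nodes):
            p *= kernels[v][st[tree.parent[v]], st[v]]
        total += p
        for v in internal:
            acc[v][st[v]] += p
    marginals = {v: acc[v][1] / total for v in internal}
    return total, marginals


def trait_matrix(tree: PhyloTree, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(columns, index=pd.Index(tree.tip_labels, name="genome"))
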