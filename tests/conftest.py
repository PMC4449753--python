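"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest
import scipy.linalg

from plumevo.characters import CharacterMatrix, PatternState, SpeciesRecord


# ---------------------------------------------------------------------------
# Independent enumeration oracle for the pruning likelihood: sums the joint
# probability over every assignment of states to internal nodes, with edge
# probabilities from scipy's expm.  Exponential in tree size; tiny trees only.


def enumeration_likelihood(tree: dendropy.Tree, states: dict[str, int],
                           Q: np.ndarray, root_prior: np.ndarray):
    """Return (log-likelihood, root posterior) by brute-force enumeration."""
    k = Q.shape[0]
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    edges = [n for n in nodes if n.parent_node is not None]
    P = {id(n): scipy.linalg.expm(Q * n.edge.length) for n in edges}
    root = tree.seed_node
    total = 0.0
    root_marginal = np.zeros(k)
    for combo in itertools.product(range(k), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        for n in nodes:
            if n.is_leaf():
                assign[id(n)] = states[n.taxon.label]
        p = root_prior[assign[id(root)]]
        for n in edges:
            p *= P[id(n)][assign[id(n.parent_node)], assign[id(n)]]
        total += p
        root_marginal[assign[id(root)]] += p
    loglik = np.log(total) if total > 0 else -np.inf
    post = root_marginal / total if total > 0 else np.full(k, np.nan)
    return loglik, post


def random_instance(rng: np.random.Generator, n_tips: int | None = None, k: int = 4):
    """A random small tree + random generator Q + random tip states."""
    from plumevo.synthetic import simulate_yule_tree

    n = n_tips if n_tips is not None else int(rng.integers(3, 6))
    tree = simulate_yule_tree(n, seed=int(rng.integers(2**31)))
    Q = rng.gamma(1.0, 0.6, size=(k, k))
    # randomly zero some transitions to exercise sparse structures
    Q[rng.random((k, k)) < 0.3] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    states = {leaf.taxon.label: int(rng.integers(k)) for leaf in tree.leaf_node_iter()}
    return tree, Q, states


def states_to_matrix(states: dict[str, int]) -> CharacterMatrix:
    return CharacterMatrix(
        [SpeciesRecord(t, state=PatternState(s)) for t, s in states.items()]
    )


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150422)


@pytest.fixture()
def small_tree():
    return dendropy.Tree.get(data="((A:1.0,B:1.0):0.5,C:2.0);", schema="newick")


@pytest.fixture()
def toy_matrix():
    """10 species with per-sex codes: counts (2, 1, 4, 3) over the states
    uniform / irregular / regular / bimodal."""
    from plumevo.characters import Motif

    none = frozenset([Motif.NONE])
    irr = frozenset([Motif.MOTTLE])
    reg = frozenset([Motif.BAR])
    both = frozenset([Motif.MOTTLE, Motif.BAR])
    specs = (
        [("u", none, none)] * 2
        + [("i", irr, irr)] * 1
        + [("r", reg, reg)] * 4
        + [("b", both, both)] * 3
    )
    records = [
        SpeciesRecord(f"{tag}{n}", male, female)
        for n, (tag, male, female) in enumerate(specs)
    ]
    return CharacterMatrix(records)
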