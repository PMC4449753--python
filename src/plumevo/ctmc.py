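"""Continuous-time Markov machinery for a k-state discrete character on a
rooted phylogeny: rate configurations, generator matrices, transition
probabilities, and the Felsenstein pruning likelihood.

A *rate configuration* assigns each of the K = k(k-1) directed transitions
either to zero (the transition does not occur) or to a shared-value rate
class; the partition of the nonzero transitions into classes plus the zero
set is the model structure explored by the reversible-jump sampler.

Because multiplying all branch lengths by c and dividing all rates by c
leaves the likelihood unchanged, rates are reported in transitions per unit
branch length of the supplied tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

import dendropy

from .characters import CharacterMatrix, PatternState

__all__ = [
    "transition_order",
    "RateConfiguration",
    "build_rate_matrix",
    "transition_matrix",
    "stationary_distribution",
    "PruningLikelihood",
    "log_likelihood",
    "root_state_probabilities",
    "uniform_root_prior",
]


def transition_order(k: int) -> list[tuple[int, int]]:
    """Canonical ordering of the K = k(k-1) directed transitions: row-major
    over ordered state pairs (i, j), i != j."""
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass(frozen=True)
class RateConfiguration:
    """Assignment of each directed transition to zero or to a rate class.

    ``assignment[t]`` is -1 for a transition fixed to zero, otherwise the
    index of its rate class; class indices must be contiguous 0..m-1, numbered
    by first appearance in the canonical transition order.  ``values[c]`` is
    the (nonnegative) rate shared by class c.
    """

    k: int
    assignment: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        K = self.k * (self.k - 1)
        if len(self.assignment) != K:
            raise ValueError(f"assignment must have length {K}, got {len(self.assignment)}")
        seen: list[int] = []
        for a in self.assignment:
            if a == -1:
                continue
            if a < 0:
                raise ValueError(f"invalid class id {a}")
            if a not in seen:
                if a != len(seen):
                    raise ValueError(
                        "class ids must be numbered by first appearance "
                        f"(saw {a} after {seen})"
                    )
                seen.append(a)
        if len(self.values) != len(seen):
            raise ValueError(
                f"{len(seen)} classes in assignment but {len(self.values)} values"
            )
        if any(v < 0 for v in self.values):
            raise ValueError("negative rate class value")

    @property
    def n_classes(self) -> int:
        return len(self.values)

    @property
    def n_zero(self) -> int:
        return sum(1 for a in self.assignment if a == -1)

    @classmethod
    def from_rates(cls, k: int, rates: dict[tuple[int, int], float]) -> "RateConfiguration":
        """Build a configuration from explicit per-transition rates; equal
        rates share a class, zero/omitted transitions are fixed to zero."""
        order = transition_order(k)
        assignment = []
        values: list[float] = []
        for pair in order:
            r = rates.get(pair, 0.0)
            if r == 0.0:
                assignment.append(-1)
            else:
                if r in values:
                    assignment.append(values.index(r))
                else:
                    values.append(r)
                    assignment.append(len(values) - 1)
        return cls(k, tuple(assignment), tuple(values))

    def rate_of(self, i: int, j: int) -> float:
        t = transition_order(self.k).index((i, j))
        a = self.assignment[t]
        return 0.0 if a == -1 else self.values[a]


def build_rate_matrix(config: RateConfiguration) -> np.ndarray:
    """Generator matrix Q: q_ij is the class value of transition i->j (0 if
    fixed to zero); the diagonal is the negative row sum."""
    k = config.k
    Q = np.zeros((k, k))
    for t, (i, j) in enumerate(transition_order(k)):
        a = config.assignment[t]
        if a != -1:
            Q[i, j] = config.values[a]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) by scaling-and-squaring; entries clipped to [0, 1]."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    P = scipy.linalg.expm(Q * t)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite entries in matrix exponential")
    return np.clip(P, 0.0, 1.0)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible generator (left null vector)."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-8):
        raise ValueError("no nonnegative stationary distribution (reducible Q?)")
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def uniform_root_prior(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


# ---------------------------------------------------------------------------
# Pruning likelihood

try:  # JIT hot path; identical pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _prune_kernel(edge_child, edge_parent, P, partial, n_tips, root_index, root_prior):
    """Tip-to-root pass over edges sorted child-before-parent.

    ``partial`` holds per-node conditional likelihood vectors (tips one-hot,
    internals initialised to 1); per-edge rescaling keeps values in range and
    the log of the scale factors is accumulated.  Returns (log-likelihood,
    unnormalised root posterior); log-likelihood is -inf for impossible data.
    """
    k = P.shape[1]
    logscale = 0.0
    v = np.empty(k)
    for e in range(edge_child.shape[0]):
        c = edge_child[e]
        p = edge_parent[e]
        pc = partial[c]
        for s in range(k):
            acc = 0.0
            for j in range(k):
                acc += P[e, s, j] * pc[j]
            v[s] = acc
        m = 0.0
        for s in range(k):
            if v[s] > m:
                m = v[s]
        if m <= 0.0:
            return -np.inf, partial[root_index].copy()
        logscale += np.log(m)
        for s in range(k):
            partial[p, s] *= v[s] / m
    total = 0.0
    root = np.empty(k)
    for s in range(k):
        root[s] = root_prior[s] * partial[root_index, s]
        total += root[s]
    if total <= 0.0:
        return -np.inf, root
    return np.log(total) + logscale, root


class PruningLikelihood:
    """Felsenstein pruning likelihood for one reconciled tree + tip states.

    The tree is flattened once into postorder edge arrays; each evaluation
    builds the per-edge transition matrices for a generator Q (by
    eigendecomposition, batched over edges, with a scipy expm fallback for
    ill-conditioned eigensystems) and runs the pruning pass.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        matrix: CharacterMatrix,
        k: int = 4,
        root_prior: np.ndarray | None = None,
    ):
        self.k = k
        self.root_prior = (
            uniform_root_prior(k) if root_prior is None else np.asarray(root_prior, float)
        )
        if self.root_prior.shape != (k,) or abs(self.root_prior.sum() - 1.0) > 1e-9:
            raise ValueError("root prior must be a length-k probability vector")
        if np.any(self.root_prior < 0):
            raise ValueError("root prior must be nonnegative")

        states = matrix.states()
        leaves = list(tree.leaf_node_iter())
        missing = [l.taxon.label for l in leaves if l.taxon.label not in states]
        if missing:
            raise ValueError(f"tips without character state: {missing[:10]}")

        postorder = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(postorder)}
        self.n_nodes = len(postorder)
        self.n_tips = len(leaves)
        self.root_index = index[id(tree.seed_node)]
        self.tip_labels = [l.taxon.label for l in leaves]

        edges = [n for n in postorder if n.parent_node is not None]
        self.edge_child = np.array([index[id(n)] for n in edges], dtype=np.int64)
        self.edge_parent = np.array([index[id(n.parent_node)] for n in edges], dtype=np.int64)
        self.edge_length = np.array([float(n.edge.length) for n in edges])
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        zero = self.edge_length == 0
        self._zero_edges = zero if zero.any() else None

        self._tip_partial = np.ones((self.n_nodes, k))
        for node in postorder:
            if node.is_leaf():
                s = states[node.taxon.label]
                value = s.value if isinstance(s, PatternState) else int(s)
                if not 0 <= value < k:
                    raise ValueError(f"tip state {value} out of range for k={k}")
                row = np.zeros(k)
                row[value] = 1.0
                self._tip_partial[index[id(node)]] = row

    # -- transition matrices for all edges at once ------------------------

    def edge_transition_matrices(self, Q: np.ndarray) -> np.ndarray:
        cond_ok = True
        try:
            lam, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            # cheap 1-norm condition estimate; large -> (near-)defective Q
            cond_ok = (
                np.abs(V).sum(axis=0).max() * np.abs(Vinv).sum(axis=0).max() < 1e10
            )
        except np.linalg.LinAlgError:
            cond_ok = False
        if cond_ok:
            # P(t) = V diag(e^{lam t}) V^-1, batched over edge lengths;
            # numpy returns real eig output whenever the spectrum is real
            elt = np.exp(self.edge_length[:, None] * lam[None, :])  # (E, k)
            P = (V[None, :, :] * elt[:, None, :]) @ Vinv
            if np.iscomplexobj(P):
                P = np.ascontiguousarray(P.real)
        else:  # defective generator: fall back to expm per edge
            P = np.stack([scipy.linalg.expm(Q * t) for t in self.edge_length])
        np.clip(P, 0.0, 1.0, out=P)
        if self._zero_edges is not None:  # exact identity at t = 0
            P[self._zero_edges] = np.eye(self.k)
        return P

    def evaluate(self, Q: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and normalised root-state posterior for Q."""
        P = self.edge_transition_matrices(Q)
        partial = self._tip_partial.copy()
        loglik, root = _prune_kernel(
            self.edge_child,
            self.edge_parent,
            P,
            partial,
            self.n_tips,
            self.root_index,
            self.root_prior,
        )
        total = root.sum()
        if np.isfinite(loglik) and total > 0:
            root = root / total
        else:
            root = np.full(self.k, np.nan)
        return float(loglik), root

    def log_likelihood(self, Q: np.ndarray) -> float:
        return self.evaluate(Q)[0]


def log_likelihood(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> float:
    """One-shot pruning log-likelihood (see :class:`PruningLikelihood`)."""
    k = Q.shape[0]
    return PruningLikelihood(tree, matrix, k=k, root_prior=root_prior).log_likelihood(Q)


def root_state_probabilities(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    Q: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior state probabilities at the root: proportional to
    root_prior[s] x L_root(s), normalised to sum to 1."""
    k = Q.shape[0]
    loglik, root = PruningLikelihood(tree, matrix, k=k, root_prior=root_prior).evaluate(Q)
    if not np.all(np.isfinite(root)):
        raise ValueError("all root partial likelihoods are zero (impossible data under Q)")
    return root
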