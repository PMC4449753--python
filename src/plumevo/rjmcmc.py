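"""Reversible-jump MCMC over rate configurations of a k-state model.

The sampler explores, jointly, (i) the model structure — which directed
transitions are fixed to zero and how the remaining ones are partitioned into
shared-value rate classes — and (ii) the rate value of each class.  The
structure prior is uniform over the Bell(K+1) distinct structures; each class
value carries a gamma prior whose shape and scale are themselves sampled
(a hyperprior), with the scale interval seeded from an empirical rate scale
(parsimony state changes per unit of total tree length).

Structural moves come in four reversible pairs — zero-out/un-zero a
transition, and merge/split rate classes — with new class values drawn from
the current gamma prior so the reversible-jump Jacobian is unity and the
acceptance ratio reduces to likelihood and proposal-count terms.  With the
likelihood switched off the chain therefore samples the uniform structure
prior exactly, which is checked by test and by the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

import dendropy

from .characters import CharacterMatrix
from .ctmc import PruningLikelihood, RateConfiguration, transition_order, uniform_root_prior

__all__ = [
    "SamplerSettings",
    "ChainState",
    "SampleRecord",
    "PosteriorSample",
    "rate_prior_logdensity",
    "propose_rate_update",
    "propose_structural_move",
    "run_chain",
    "run_chains",
    "merge_samples",
    "fitch_parsimony_changes",
    "empirical_rate_scale",
    "write_samples_tsv",
    "read_samples_tsv",
]


@dataclass(frozen=True)
class SamplerSettings:
    """Chain-length, proposal, and prior settings.

    Full-scale defaults: 10,050,000 iterations per chain,
    50,000 burn-in, sampling every 1000th model then every 20th retained
    model, four chains, with the rate-proposal scale (``ratedev``) adapted
    during burn-in to hold acceptance between 0.20 and 0.40.  Use
    :meth:`desk_scale` for the test-scale profile.
    """

    iterations: int = 10_050_000
    burn_in: int = 50_000
    sample_every: int = 1000
    post_thin: int = 20
    n_chains: int = 4
    ratedev: float = 0.2
    acceptance_window: tuple[float, float] = (0.20, 0.40)
    rate_move_prob: float = 0.6
    hyper_update_every: int = 10
    # shape >= 1 keeps the gamma density finite at zero, so a "positive" rate
    # collapsing onto 0 cannot mimic a zero-rate model for free
    shape_interval: tuple[float, float] = (1.0, 2.0)
    scale_interval: tuple[float, float] | None = None  # None: (eps, 2 x empirical scale)
    adapt_every: int = 200
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.sample_every < 1 or self.post_thin < 1:
            raise ValueError("sample_every and post_thin must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "SamplerSettings":
        """Short-chain profile (200k iterations, 5k burn-in) for routine use."""
        base = dict(iterations=200_000, burn_in=5_000, sample_every=100, post_thin=2)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper_scale(cls, **overrides) -> "SamplerSettings":
        return cls(**overrides)

    @property
    def retained_per_chain(self) -> int:
        kept = (self.iterations - self.burn_in) // self.sample_every
        return kept // self.post_thin


@dataclass
class ChainState:
    """Mutable sampler state: structure, class values, hyperparameters."""

    k: int
    assignment: np.ndarray  # length K; -1 = zero, else class index (canonical)
    values: list[float]
    loglik: float
    root: np.ndarray
    hyper_shape: float
    hyper_scale: float
    accept_counts: dict = field(default_factory=lambda: {
        "rate": [0, 0], "structural": [0, 0], "hyper": [0, 0]})

    @property
    def n_classes(self) -> int:
        return len(self.values)

    def to_configuration(self) -> RateConfiguration:
        return RateConfiguration(self.k, tuple(int(a) for a in self.assignment),
                                 tuple(self.values))


@dataclass(frozen=True)
class SampleRecord:
    assignment: tuple[int, ...]
    values: tuple[float, ...]
    loglik: float
    root: tuple[float, ...]

    def to_configuration(self, k: int) -> RateConfiguration:
        return RateConfiguration(k, self.assignment, self.values)


@dataclass
class PosteriorSample:
    """Thinned retained sample of one chain (or a merged set of chains)."""

    k: int
    records: list[SampleRecord]
    chain_id: int
    settings: SamplerSettings
    acceptance: dict = field(default_factory=dict)
    ratedev_final: float = float("nan")
    likelihood_on: bool = True

    def __len__(self) -> int:
        return len(self.records)

    @property
    def logliks(self) -> np.ndarray:
        return np.array([r.loglik for r in self.records])


# ---------------------------------------------------------------------------
# Priors


def rate_prior_logdensity(value: float, shape: float, scale: float) -> float:
    """Gamma log-density of a rate value under hyperparameters (shape, scale)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma hyperparameters must be positive")
    if value < 0:
        return -math.inf
    if value == 0.0:
        # finite only for the exponential special case shape == 1
        if shape == 1.0:
            return -math.log(scale)
        return math.inf if shape < 1.0 else -math.inf
    return (shape - 1.0) * math.log(value) - value / scale - gammaln(shape) - shape * math.log(scale)


def fitch_parsimony_changes(tree: dendropy.Tree, states: dict[str, int]) -> int:
    """Fitch parsimony count of state changes (polytomies handled by
    sequential child merging)."""
    changes = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            sets[id(node)] = frozenset([int(s.value) if hasattr(s, "value") else int(s)])
        else:
            cur = None
            for child in node.child_nodes():
                cs = sets[id(child)]
                if cur is None:
                    cur = cs
                else:
                    inter = cur & cs
                    if inter:
                        cur = inter
                    else:
                        cur = cur | cs
                        changes += 1
            sets[id(node)] = cur
    return changes


def empirical_rate_scale(tree: dendropy.Tree, matrix: CharacterMatrix) -> float:
    """Crude rate scale: parsimony changes / total tree length."""
    from .trees import total_tree_length

    states = {t: s for t, s in matrix.states().items()}
    changes = max(fitch_parsimony_changes(tree, states), 1)
    return changes / total_tree_length(tree)


# ---------------------------------------------------------------------------
# Proposals


def _canonicalize(assignment: np.ndarray, values: Sequence[float]) -> tuple[np.ndarray, list[float]]:
    """Renumber classes by first appearance in transition order."""
    relabel: dict[int, int] = {}
    new_assign = assignment.copy()
    for t, a in enumerate(assignment):
        if a == -1:
            continue
        if a not in relabel:
            relabel[a] = len(relabel)
        new_assign[t] = relabel[a]
    new_values = [0.0] * len(relabel)
    for old, new in relabel.items():
        new_values[new] = values[old]
    return new_assign, new_values


def _class_sizes(assignment: np.ndarray, m: int) -> np.ndarray:
    sizes = np.zeros(m, dtype=np.int64)
    for a in assignment:
        if a != -1:
            sizes[a] += 1
    return sizes


def _n_valid_types(K_nz: int, K_z: int, m: int, n_splittable: int) -> int:
    return (K_nz >= 1) + (K_z >= 1) + (m >= 2) + (n_splittable >= 1)


def propose_rate_update(state: ChainState, ratedev: float, rng: np.random.Generator):
    """Perturb one class value by a reflected symmetric uniform kernel.

    Returns (class index, proposed value); the Hastings ratio of the
    reflected kernel is 1.
    """
    if state.n_classes == 0:
        raise ValueError("no rate classes to update")
    c = int(rng.integers(state.n_classes))
    new_value = abs(state.values[c] + rng.uniform(-ratedev, ratedev))
    return c, new_value


def propose_structural_move(state: ChainState, rng: np.random.Generator):
    """Propose one reversible-jump structural move.

    Move types, chosen uniformly among those currently valid:
    zero-out a transition; un-zero a transition into an existing or new class
    (new value drawn from the current gamma prior); merge two classes
    (discarding one value); split a class (drawing one new value).

    Returns (new_assignment, new_values, log_accept_adjust) where
    ``log_accept_adjust`` collects the proposal-count and dimension-matching
    terms — value-prior densities cancel exactly because new values are drawn
    from the prior — so the MH acceptance is ``delta_loglik + adjust``.
    """
    assign = state.assignment
    values = state.values
    m = len(values)
    K = assign.shape[0]
    K_nz = int(np.sum(assign != -1))
    K_z = K - K_nz
    sizes = _class_sizes(assign, m)
    splittable = np.flatnonzero(sizes >= 2)
    T_x = _n_valid_types(K_nz, K_z, m, len(splittable))

    types = []
    if K_nz >= 1:
        types.append("zero_out")
    if K_z >= 1:
        types.append("unzero")
    if m >= 2:
        types.append("merge")
    if len(splittable) >= 1:
        types.append("split")
    move = types[int(rng.integers(len(types)))]

    draw_rate = lambda: float(rng.gamma(state.hyper_shape, state.hyper_scale))

    if move == "zero_out":
        nz = np.flatnonzero(assign != -1)
        t = int(nz[rng.integers(len(nz))])
        c = int(assign[t])
        new_assign = assign.copy()
        new_assign[t] = -1
        new_values = list(values)
        emptied = sizes[c] == 1
        if emptied:
            del new_values[c]
            new_assign[new_assign > c] -= 1
        new_assign, new_values = _canonicalize(new_assign, new_values)
        m2 = len(new_values)
        sizes2 = _class_sizes(new_assign, m2)
        T_xp = _n_valid_types(K_nz - 1, K_z + 1, m2, int(np.sum(sizes2 >= 2)))
        log_fwd = -math.log(T_x) - math.log(K_nz)
        log_rev = -math.log(T_xp) - math.log(K_z + 1) - math.log(m2 + 1)
        return new_assign, new_values, log_rev - log_fwd

    if move == "unzero":
        z = np.flatnonzero(assign == -1)
        t = int(z[rng.integers(len(z))])
        target = int(rng.integers(m + 1))  # m existing classes or a new one
        new_assign = assign.copy()
        new_values = list(values)
        if target == m:
            new_values.append(draw_rate())
        new_assign[t] = target
        new_assign, new_values = _canonicalize(new_assign, new_values)
        m2 = len(new_values)
        sizes2 = _class_sizes(new_assign, m2)
        T_xp = _n_valid_types(K_nz + 1, K_z - 1, m2, int(np.sum(sizes2 >= 2)))
        log_fwd = -math.log(T_x) - math.log(K_z) - math.log(m + 1)
        log_rev = -math.log(T_xp) - math.log(K_nz + 1)
        return new_assign, new_values, log_rev - log_fwd

    if move == "merge":
        c, d = rng.choice(m, size=2, replace=False)
        c, d = int(c), int(d)
        keep_c = bool(rng.integers(2))
        kept, gone = (c, d) if keep_c else (d, c)
        n = int(sizes[c] + sizes[d])
        new_assign = assign.copy()
        new_assign[new_assign == gone] = kept
        new_values = list(values)
        del new_values[gone]
        new_assign[new_assign > gone] -= 1
        new_assign, new_values = _canonicalize(new_assign, new_values)
        m2 = m - 1
        sizes2 = _class_sizes(new_assign, m2)
        n_split2 = int(np.sum(sizes2 >= 2))
        T_xp = _n_valid_types(K_nz, K_z, m2, n_split2)
        log_fwd = -math.log(T_x) - math.log(m * (m - 1) / 2) - math.log(2)
        log_rev = (-math.log(T_xp) - math.log(n_split2)
                   - math.log(2 ** (n - 1) - 1) - math.log(2))
        return new_assign, new_values, log_rev - log_fwd

    # split
    c = int(splittable[rng.integers(len(splittable))])
    members = np.flatnonzero(assign == c)
    n = len(members)
    while True:  # uniform over proper bipartitions by rejection
        side = rng.integers(2, size=n)
        if 0 < side.sum() < n:
            break
    new_assign = assign.copy()
    new_values = list(values)
    new_class = m
    new_assign[members[side == 1]] = new_class
    w = draw_rate()
    if rng.integers(2):  # which part receives the freshly drawn value
        new_values.append(w)
    else:
        new_values.append(new_values[c])
        new_values[c] = w
    new_assign, new_values = _canonicalize(new_assign, new_values)
    m2 = m + 1
    sizes2 = _class_sizes(new_assign, m2)
    T_xp = _n_valid_types(K_nz, K_z, m2, int(np.sum(sizes2 >= 2)))
    log_fwd = (-math.log(T_x) - math.log(len(splittable))
               - math.log(2 ** (n - 1) - 1) - math.log(2))
    log_rev = -math.log(T_xp) - math.log(m2 * (m2 - 1) / 2) - math.log(2)
    return new_assign, new_values, log_rev - log_fwd


# ---------------------------------------------------------------------------
# Chain driver


def _build_Q(k: int, assignment: np.ndarray, values: Sequence[float],
             idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    Q = np.zeros((k, k))
    vals = np.asarray(values)
    mask = assignment != -1
    if mask.any():
        Q[idx_i[mask], idx_j[mask]] = vals[assignment[mask]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def run_chain(
    tree: dendropy.Tree | None,
    matrix: CharacterMatrix | None,
    settings: SamplerSettings,
    likelihood_on: bool = True,
    k: int = 4,
    root_prior: np.ndarray | None = None,
    chain_id: int = 0,
    seed: int | None = None,
    max_init_retries: int = 20,
) -> PosteriorSample:
    """Run one RJMCMC chain and return the thinned retained sample.

    With ``likelihood_on=False`` the chain targets the prior alone (tree and
    matrix may be None); this is the prior-recovery mode.  Deterministic for
    a given seed.  ``ratedev`` is adapted only during burn-in, in blocks of
    ``settings.adapt_every`` iterations, to keep rate-move acceptance inside
    ``settings.acceptance_window``, and is frozen afterwards.
    """
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    K = k * (k - 1)
    order = transition_order(k)
    idx_i = np.array([i for i, _ in order])
    idx_j = np.array([j for _, j in order])

    if likelihood_on:
        if tree is None or matrix is None:
            raise ValueError("tree and matrix are required when the likelihood is on")
        evaluator = PruningLikelihood(tree, matrix, k=k, root_prior=root_prior)
        scale0 = empirical_rate_scale(tree, matrix)
    else:
        evaluator = None
        scale0 = 1.0
    root0 = uniform_root_prior(k) if root_prior is None else np.asarray(root_prior, float)

    lo_s, hi_s = settings.shape_interval
    if settings.scale_interval is not None:
        lo_c, hi_c = settings.scale_interval
    else:
        hi_c = 2.0 * scale0
        lo_c = 1e-6 * hi_c
    if lo_s <= 0 or lo_c <= 0:
        raise ValueError("hyperprior intervals must be positive")

    def _gamma_logpdf(v: float, shape: float, scale: float) -> float:
        return rate_prior_logdensity(v, shape, scale)

    # initialise: equal-rates model (all transitions in one class)
    for attempt in range(max_init_retries):
        state = ChainState(
            k=k,
            assignment=np.zeros(K, dtype=np.int64),
            values=[scale0 * float(rng.uniform(0.5, 2.0))],
            loglik=0.0,
            root=root0.copy(),
            hyper_shape=float(rng.uniform(lo_s, hi_s)),
            hyper_scale=float(rng.uniform(lo_c, hi_c)),
        )
        if not likelihood_on:
            break
        Q = _build_Q(k, state.assignment, state.values, idx_i, idx_j)
        state.loglik, state.root = evaluator.evaluate(Q)
        if math.isfinite(state.loglik):
            break
    else:
        raise RuntimeError("could not find a finite-likelihood initial state")

    ratedev = settings.ratedev
    lo_acc, hi_acc = settings.acceptance_window
    window_acc = [0, 0]
    records: list[SampleRecord] = []

    def _reflect(v: float, lo: float, hi: float) -> float:
        width = hi - lo
        if width <= 0:  # degenerate interval pins the hyperparameter
            return lo
        v = (v - lo) % (2 * width)
        return lo + (v if v <= width else 2 * width - v)

    for it in range(1, settings.iterations + 1):
        # The 60/40 rate/structural mixture must not depend on the state, or
        # the mixture weights would enter the Hastings ratio; a rate move
        # drawn while no class exists is therefore a null iteration.
        is_rate = rng.random() < settings.rate_move_prob
        if is_rate and state.n_classes == 0:
            pass
        elif not is_rate:
            # structural move
            new_assign, new_values, adjust = propose_structural_move(state, rng)
            if likelihood_on:
                Q = _build_Q(k, new_assign, new_values, idx_i, idx_j)
                new_loglik, new_root = evaluator.evaluate(Q)
            else:
                new_loglik, new_root = 0.0, state.root
            state.accept_counts["structural"][1] += 1
            log_alpha = (new_loglik - state.loglik) + adjust
            if math.isfinite(new_loglik) and math.log(rng.random()) < log_alpha:
                state.assignment, state.values = new_assign, new_values
                state.loglik, state.root = new_loglik, new_root
                state.accept_counts["structural"][0] += 1
        else:  # rate-value update
            c, new_value = propose_rate_update(state, ratedev, rng)
            old_value = state.values[c]
            dprior = (_gamma_logpdf(new_value, state.hyper_shape, state.hyper_scale)
                      - _gamma_logpdf(old_value, state.hyper_shape, state.hyper_scale))
            state.values[c] = new_value
            if likelihood_on:
                Q = _build_Q(k, state.assignment, state.values, idx_i, idx_j)
                new_loglik, new_root = evaluator.evaluate(Q)
            else:
                new_loglik, new_root = 0.0, state.root
            state.accept_counts["rate"][1] += 1
            window_acc[1] += 1
            log_alpha = (new_loglik - state.loglik) + dprior
            if math.isfinite(new_loglik) and math.log(rng.random()) < log_alpha:
                state.loglik, state.root = new_loglik, new_root
                state.accept_counts["rate"][0] += 1
                window_acc[0] += 1
            else:
                state.values[c] = old_value

        if settings.hyper_update_every and it % settings.hyper_update_every == 0:
            new_shape = _reflect(state.hyper_shape + rng.uniform(-0.1, 0.1) * (hi_s - lo_s),
                                 lo_s, hi_s)
            new_scale = _reflect(state.hyper_scale + rng.uniform(-0.1, 0.1) * (hi_c - lo_c),
                                 lo_c, hi_c)
            state.accept_counts["hyper"][1] += 1
            dlog = sum(
                _gamma_logpdf(v, new_shape, new_scale)
                - _gamma_logpdf(v, state.hyper_shape, state.hyper_scale)
                for v in state.values
            )
            if math.log(rng.random()) < dlog:
                state.hyper_shape, state.hyper_scale = new_shape, new_scale
                state.accept_counts["hyper"][0] += 1

        # ratedev adaptation, burn-in only
        if it <= settings.burn_in and it % settings.adapt_every == 0 and window_acc[1] >= 20:
            acc = window_acc[0] / window_acc[1]
            if acc < lo_acc:
                ratedev = max(ratedev * 0.7, 1e-8)
            elif acc > hi_acc:
                ratedev = min(ratedev * 1.4, 1e4)
            window_acc = [0, 0]

        if it > settings.burn_in and (it - settings.burn_in) % settings.sample_every == 0:
            records.append(
                SampleRecord(
                    tuple(int(a) for a in state.assignment),
                    tuple(float(v) for v in state.values),
                    float(state.loglik),
                    tuple(float(r) for r in state.root),
                )
            )

    retained = records[settings.post_thin - 1 :: settings.post_thin]
    acceptance = {
        name: (acc / max(tot, 1)) for name, (acc, tot) in state.accept_counts.items()
    }
    return PosteriorSample(
        k=k,
        records=retained,
        chain_id=chain_id,
        settings=settings,
        acceptance=acceptance,
        ratedev_final=ratedev,
        likelihood_on=likelihood_on,
    )


def run_chains(
    tree: dendropy.Tree | None,
    matrix: CharacterMatrix | None,
    settings: SamplerSettings,
    likelihood_on: bool = True,
    k: int = 4,
    root_prior: np.ndarray | None = None,
) -> list[PosteriorSample]:
    """Run ``settings.n_chains`` independent chains with seeds derived from
    ``settings.seed``."""
    seeds = np.random.SeedSequence(settings.seed).generate_state(settings.n_chains) % (2**31)
    return [
        run_chain(
            tree, matrix, settings,
            likelihood_on=likelihood_on, k=k, root_prior=root_prior,
            chain_id=i, seed=int(s),
        )
        for i, s in enumerate(seeds)
    ]


def merge_samples(samples: Sequence[PosteriorSample]) -> PosteriorSample:
    if not samples:
        raise ValueError("no samples to merge")
    k = samples[0].k
    if any(s.k != k for s in samples):
        raise ValueError("inconsistent state counts across chains")
    records = [r for s in samples for r in s.records]
    return PosteriorSample(
        k=k,
        records=records,
        chain_id=-1,
        settings=samples[0].settings,
        acceptance={},
        likelihood_on=samples[0].likelihood_on,
    )


# ---------------------------------------------------------------------------
# Sample I/O (TSV)


def write_samples_tsv(samples: Sequence[PosteriorSample], path) -> None:
    """One row per retained model: chain, index, per-transition assignment,
    class values, log-likelihood, root-state probabilities."""
    with open(path, "w") as fh:
        fh.write("chain\tindex\tassignment\tvalues\tlogL\troot\n")
        for s in samples:
            for i, r in enumerate(s.records):
                fh.write(
                    f"{s.chain_id}\t{i}\t"
                    + ",".join(str(a) for a in r.assignment)
                    + "\t"
                    + ",".join(f"{v:.12g}" for v in r.values)
                    + f"\t{r.loglik:.12g}\t"
                    + ",".join(f"{p:.12g}" for p in r.root)
                    + "\n"
                )


def read_samples_tsv(path, k: int = 4) -> list[PosteriorSample]:
    chains: dict[int, list[SampleRecord]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chain", "index", "assignment", "values", "logL", "root"]
        if header != expected:
            raise ValueError(f"{path}: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                chain = int(parts[0])
                assignment = tuple(int(a) for a in parts[2].split(","))
                values = tuple(float(v) for v in parts[3].split(",")) if parts[3] else ()
                loglik = float(parts[4])
                root = tuple(float(p) for p in parts[5].split(","))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: parse error: {exc}") from exc
            chains.setdefault(chain, []).append(
                SampleRecord(assignment, values, loglik, root)
            )
    settings = SamplerSettings.desk_scale()
    return [
        PosteriorSample(k=k, records=recs, chain_id=cid, settings=settings)
        for cid, recs in sorted(chains.items())
    ]
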