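"""Synthetic phylogenies and pattern data with the statistical structure the
analysis assumes.

Trees are pure-birth (Yule) trees standing in for published order-level
phylogenies; characters evolve along them under a 4-state continuous-time
Markov process whose generator is a named preset of zero / positive
transition structures (including structures in which bimodal patterning can
only be reached via the singular irregular or regular types).  Tip states can
be decomposed into per-sex motif codes consistent with the classification
rules, with the three bimodal sex-phenotype categories drawn at a
configurable ratio (default 51 : 37 : 12 — both sexes bimodal : one sex
bimodal : complementary singular patterns).
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import dendropy
from dendropy.simulate import treesim

from .characters import CharacterMatrix, Motif, PatternState, SpeciesRecord
from .ctmc import RateConfiguration, build_rate_matrix

__all__ = [
    "GeneratorPreset",
    "PRESETS",
    "get_preset",
    "simulate_yule_tree",
    "simulate_character",
    "make_dataset",
]

U, I, R, B = 0, 1, 2, 3  # uniform, irregular, regular, bimodal

#: default bimodal sex-phenotype category ratio (same : one-sex-bimodal : split)
BIMODAL_CATEGORY_RATIO = (0.51, 0.37, 0.12)

#: probability that a singular-patterned species is patterned in one sex only
SEX_LIMITED_PATTERN_PROB = 0.3


@dataclass(frozen=True)
class GeneratorPreset:
    """A named ground-truth scenario: rate structure, root state, tree size."""

    name: str
    config: RateConfiguration
    root_state: int
    n_tips: int
    birth_rate: float = 1.0
    seed: int = 0


def _config(rates: dict) -> RateConfiguration:
    return RateConfiguration.from_rates(4, rates)


# Rate magnitudes are set so a root-to-tip path expects roughly three state
# changes on a Yule tree of 100-200 tips with unit birth rate (height ~ ln n).
_HI, _MID, _LO = 0.35, 0.25, 0.18

PRESETS: dict[str, GeneratorPreset] = {
    # gains of pattern complexity and their reversals; no direct shortcut
    # between uniform and bimodal, no irregular <-> regular interchange
    "fig2_hypothesis": GeneratorPreset(
        "fig2_hypothesis",
        _config({(U, I): _HI, (U, R): _HI, (I, B): _HI, (R, B): _HI,
                 (I, U): _LO, (R, U): _LO, (B, I): _LO, (B, R): _LO}),
        root_state=U, n_tips=150,
    ),
    # regular/bimodal arise directly from uniform; irregular only via bimodal;
    # regular never degrades to irregular, nor feeds bimodal
    "anseriformes_like": GeneratorPreset(
        "anseriformes_like",
        _config({(U, R): _HI, (U, B): _HI, (I, R): _MID, (I, B): _MID,
                 (B, I): _MID, (B, R): _MID, (R, U): _LO, (B, U): _LO}),
        root_state=U, n_tips=118,
    ),
    # irregular and regular arise from uniform, bimodal only via the singular
    # types; no direct uniform <-> bimodal, no regular -> irregular
    "galliformes_like": GeneratorPreset(
        "galliformes_like",
        _config({(U, I): _HI, (U, R): _HI, (I, B): _HI, (R, B): _HI,
                 (I, R): _MID, (I, U): _LO, (R, U): _LO, (B, I): _LO, (B, R): _LO}),
        root_state=U, n_tips=170,
    ),
    # galliformes-like structure at one third the pace (~1 expected change per
    # root-to-tip path): slow enough that the root state remains identifiable,
    # for ancestral-state recovery demonstrations
    "root_informative": GeneratorPreset(
        "root_informative",
        _config({(U, I): _HI / 3, (U, R): _HI / 3, (I, B): _HI / 3, (R, B): _HI / 3,
                 (I, R): _MID / 3, (I, U): _LO / 3, (R, U): _LO / 3,
                 (B, I): _LO / 3, (B, R): _LO / 3}),
        root_state=U, n_tips=170,
    ),
    "full_model": GeneratorPreset(
        "full_model",
        _config({(i, j): _MID for i in range(4) for j in range(4) if i != j}),
        root_state=U, n_tips=150,
    ),
    "null_uniform": GeneratorPreset(
        "null_uniform", _config({}), root_state=U, n_tips=150,
    ),
}


def get_preset(name: str) -> GeneratorPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant tips labeled t001..tNNN.

    Branch lengths are in time units of the birth process; deterministic for
    a given seed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.is_rooted = True
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:0{width}d}"
    return tree


def _simulate_branch(state: int, length: float, Q: np.ndarray, rng: np.random.Generator) -> int:
    """Exact stochastic simulation of the chain along one branch."""
    t = 0.0
    k = Q.shape[0]
    while True:
        out_rate = -Q[state, state]
        if out_rate <= 0.0:
            return state
        t += rng.exponential(1.0 / out_rate)
        if t >= length:
            return state
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(k, p=probs))


_REGULAR_CHOICES = (Motif.BAR, Motif.SCALE, Motif.SPOT)


def _decompose_sexes(
    state: int,
    rng: np.random.Generator,
    bimodal_ratio=BIMODAL_CATEGORY_RATIO,
    sex_limited_prob: float = SEX_LIMITED_PATTERN_PROB,
) -> tuple[frozenset, frozenset]:
    """Per-sex motif codes consistent with a species-level state."""
    reg = lambda: frozenset([_REGULAR_CHOICES[rng.integers(3)]])
    irr = lambda: frozenset([Motif.MOTTLE])
    both = lambda: frozenset([Motif.MOTTLE, _REGULAR_CHOICES[rng.integers(3)]])
    none = frozenset([Motif.NONE])

    if state == U:
        return none, none
    if state in (I, R):
        patterned = irr() if state == I else reg()
        other = none if rng.random() < sex_limited_prob else (
            irr() if state == I else reg())
        return (patterned, other) if rng.random() < 0.5 else (other, patterned)
    # bimodal: draw one of the three sex-phenotype categories
    cat = int(rng.choice(3, p=np.asarray(bimodal_ratio) / sum(bimodal_ratio)))
    if cat == 0:  # both sexes individually bimodal
        return both(), both()
    if cat == 1:  # one sex bimodal, the other singular
        singular = irr() if rng.random() < 0.5 else reg()
        pair = (both(), singular)
    else:  # complementary: one regular, the other irregular
        pair = (reg(), irr())
    return pair if rng.random() < 0.5 else (pair[1], pair[0])


def simulate_character(
    tree: dendropy.Tree,
    config: RateConfiguration,
    root_state: int = 0,
    seed: int = 0,
    decompose_sexes: bool = True,
    bimodal_ratio=BIMODAL_CATEGORY_RATIO,
) -> CharacterMatrix:
    """Evolve the pattern character along the tree (exact simulation with
    exponential waiting times) and return a CharacterMatrix of tip states,
    optionally decomposed into per-sex motif codes."""
    k = config.k
    if not 0 <= root_state < k:
        raise ValueError(f"root state {root_state} out of range for k={k}")
    Q = build_rate_matrix(config)
    rng = np.random.default_rng(seed)
    node_state: dict[int, int] = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_state = node_state[id(node.parent_node)]
        node_state[id(node)] = _simulate_branch(
            parent_state, float(node.edge.length), Q, rng
        )
    records = []
    for leaf in tree.leaf_node_iter():
        state = PatternState(node_state[id(leaf)])
        if decompose_sexes and k == 4:
            male, female = _decompose_sexes(state.value, rng, bimodal_ratio)
            records.append(SpeciesRecord(leaf.taxon.label, male, female))
        else:
            records.append(SpeciesRecord(leaf.taxon.label, state=state))
    return CharacterMatrix(records)


def make_dataset(
    preset: GeneratorPreset | str,
    out_dir: str | Path,
    n_tips: int | None = None,
    seed: int | None = None,
) -> dict:
    """Write a complete synthetic dataset: Newick tree, character CSV, and a
    truth JSON (true configuration, root state, seeds) for recovery scoring.

    Returns the truth record as a dict (also written to ``truth.json``).
    """
    from .characters import write_character_csv

    if isinstance(preset, str):
        preset = get_preset(preset)
    n = n_tips if n_tips is not None else preset.n_tips
    s = seed if seed is not None else preset.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = simulate_yule_tree(n, preset.birth_rate, seed=s)
    matrix = simulate_character(tree, preset.config, preset.root_state, seed=s + 1)

    tree_path = out / f"{preset.name}.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    csv_path = out / f"{preset.name}_characters.csv"
    write_character_csv(matrix, csv_path)

    truth = {
        "preset": preset.name,
        "n_tips": n,
        "birth_rate": preset.birth_rate,
        "root_state": preset.root_state,
        "seed": s,
        "k": preset.config.k,
        "assignment": list(preset.config.assignment),
        "values": list(preset.config.values),
        "tree": tree_path.name,
        "characters": csv_path.name,
    }
    with open(out / f"{preset.name}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def truth_to_configuration(truth: dict) -> RateConfiguration:
    """Round-trip a truth record back into a RateConfiguration."""
    return RateConfiguration(
        truth["k"], tuple(truth["assignment"]), tuple(truth["values"])
    )
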