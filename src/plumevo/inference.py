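"""Multimodel inference over the RJMCMC posterior sample.

Each retained model is reduced to a canonical *signature* — which transitions
are fixed to zero and how the remaining ones are partitioned into rate
classes, with classes numbered by first appearance.  The model space of K
directed transitions contains sum_z C(K, z) * Bell(K - z) = Bell(K + 1)
distinct signatures; the prior over signatures is uniform.  For each unique
sampled model, the posterior probability is its sample frequency, and the
Bayes factor is posterior/prior; models with BF >= 2 form the *top model
set*.  Per-transition marginal probabilities (of being fixed to zero versus
positive) and frequency-weighted mean rates summarise either the full sample
or the top set — the reference set is recorded in every output.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .ctmc import RateConfiguration, transition_order
from .rjmcmc import PosteriorSample, SampleRecord

__all__ = [
    "canonical_signature",
    "bell_number",
    "model_space_size",
    "prior_probability",
    "ModelScore",
    "score_models",
    "top_model_set",
    "TransitionSummary",
    "marginal_probabilities",
    "ancestral_average",
    "export_transition_graph",
]


def canonical_signature(config: RateConfiguration | Sequence[int]) -> str:
    """Canonical string signature of a structure: 'Z' per zero transition,
    otherwise the class index renumbered by first appearance.  Two
    configurations differing only by class relabeling share a signature."""
    assignment = config.assignment if isinstance(config, RateConfiguration) else config
    relabel: dict[int, int] = {}
    out = []
    for a in assignment:
        if a == -1:
            out.append("Z")
        else:
            if a not in relabel:
                relabel[a] = len(relabel)
            out.append(str(relabel[a]))
    return ",".join(out)


@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """Bell number by the Bell-triangle recurrence (exact integers)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def model_space_size(K: int) -> int:
    """Number of distinct structures of K transitions:
    sum over z of C(K, z) * Bell(K - z), which equals Bell(K + 1)."""
    total = 0
    for z in range(K + 1):
        total += math.comb(K, z) * bell_number(K - z)
    return total


def prior_probability(signature: str, K: int) -> float:
    """Uniform prior over the model space: 1 / Bell(K + 1) per signature."""
    if signature.count(",") + 1 != K:
        raise ValueError(f"signature has {signature.count(',') + 1} transitions, expected {K}")
    return 1.0 / model_space_size(K)


@dataclass(frozen=True)
class ModelScore:
    signature: str
    frequency: int
    posterior: float
    prior: float
    bayes_factor: float
    mean_loglik: float


def score_models(sample: PosteriorSample) -> list[ModelScore]:
    """Score each unique sampled structure: posterior = frequency / sample
    size; BF = posterior / prior.  Sorted by posterior descending."""
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    K = sample.k * (sample.k - 1)
    prior = 1.0 / model_space_size(K)
    n = len(sample)
    sigs = [canonical_signature(r.assignment) for r in sample.records]
    counts = Counter(sigs)
    loglik_sum: dict[str, float] = Counter()
    for sig, r in zip(sigs, sample.records):
        loglik_sum[sig] += r.loglik
    scores = []
    for sig, freq in counts.items():
        post = freq / n
        scores.append(
            ModelScore(sig, freq, post, prior, post / prior, loglik_sum[sig] / freq)
        )
    scores.sort(key=lambda s: (-s.posterior, s.signature))
    return scores


def top_model_set(scores: Iterable[ModelScore], bf_threshold: float = 2.0,
                  log_scale: bool = False) -> list[ModelScore]:
    """Models with BF >= threshold (positive evidence), sorted by BF
    descending.  With ``log_scale`` the threshold applies to 2 ln BF."""
    out = []
    for s in scores:
        bf = 2.0 * math.log(s.bayes_factor) if (log_scale and s.bayes_factor > 0) else s.bayes_factor
        if bf >= bf_threshold:
            out.append(s)
    out.sort(key=lambda s: -s.bayes_factor)
    if not out:
        warnings.warn("top model set is empty (no model with BF >= threshold)", stacklevel=2)
    return out


@dataclass
class TransitionSummary:
    """Per-transition marginals over a stated reference set.

    ``mp_zero[t]``/``mp_positive[t]`` are the frequency-weighted probabilities
    that transition t is fixed to zero / takes a positive value;
    ``mean_rate[t]`` is the weighted mean rate over models where it is
    positive (NaN if never positive).  Over the full sample the two marginals
    sum to 1 per transition; over the top model set they need not.
    """

    k: int
    reference_set: str  # "full_sample" or "top_model_set"
    total_weight: int
    mp_zero: np.ndarray
    mp_positive: np.ndarray
    mean_rate: np.ndarray

    @property
    def transitions(self) -> list[tuple[int, int]]:
        return transition_order(self.k)

    def to_dict(self, state_names: Sequence[str] | None = None) -> dict:
        names = state_names or [str(i) for i in range(self.k)]
        rows = {}
        for t, (i, j) in enumerate(self.transitions):
            rows[f"{names[i]}->{names[j]}"] = {
                "mp_zero": float(self.mp_zero[t]),
                "mp_positive": float(self.mp_positive[t]),
                "mean_rate": None if math.isnan(self.mean_rate[t]) else float(self.mean_rate[t]),
            }
        return {"reference_set": self.reference_set, "total_weight": self.total_weight,
                "transitions": rows}


def marginal_probabilities(
    sample: PosteriorSample,
    reference: str = "full_sample",
    bf_threshold: float = 2.0,
) -> TransitionSummary:
    """Cumulative per-transition marginal probabilities and mean rates.

    ``reference`` selects the weighting set: ``full_sample`` uses every
    retained model once; ``top_model_set`` restricts to retained models whose
    signature has BF >= threshold.
    """
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    if reference not in ("full_sample", "top_model_set"):
        raise ValueError(f"unknown reference set {reference!r}")
    records = sample.records
    if reference == "top_model_set":
        top = {s.signature for s in top_model_set(score_models(sample), bf_threshold)}
        records = [r for r in records if canonical_signature(r.assignment) in top]
        if not records:
            raise ValueError("top model set contains no retained models")
    K = sample.k * (sample.k - 1)
    n = len(records)
    zero_count = np.zeros(K)
    pos_count = np.zeros(K)
    rate_sum = np.zeros(K)
    for r in records:
        for t, a in enumerate(r.assignment):
            if a == -1:
                zero_count[t] += 1
            else:
                pos_count[t] += 1
                rate_sum[t] += r.values[a]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rate = np.where(pos_count > 0, rate_sum / np.maximum(pos_count, 1), np.nan)
    denom = len(sample)  # marginals relative to the full retained sample size
    return TransitionSummary(
        k=sample.k,
        reference_set=reference,
        total_weight=n,
        mp_zero=zero_count / denom,
        mp_positive=pos_count / denom,
        mean_rate=mean_rate,
    )


def ancestral_average(sample: PosteriorSample) -> np.ndarray:
    """Arithmetic mean of per-model root-state probability vectors."""
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    roots = np.array([r.root for r in sample.records])
    avg = roots.mean(axis=0)
    return avg / avg.sum()


def export_transition_graph(
    summary: TransitionSummary,
    path=None,
    state_names: Sequence[str] | None = None,
    max_penwidth: float = 6.0,
) -> str:
    """Render the transition summary as a DOT digraph.

    Edges are black ("occurs") when the marginal probability of a positive
    rate exceeds that of being zero, gray otherwise; width is proportional to
    the mean rate; each edge is labeled with (MP zero / MP positive).
    Returns the DOT text and optionally writes it to ``path``.
    """
    names = list(state_names or ["uniform", "irregular", "regular", "bimodal"][: summary.k])
    if len(names) != summary.k:
        raise ValueError(f"need {summary.k} state names")
    finite = summary.mean_rate[~np.isnan(summary.mean_rate)]
    rate_max = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    lines = [
        "digraph transitions {",
        f'  // reference set: {summary.reference_set} (n={summary.total_weight})',
        "  rankdir=LR;",
        '  node [shape=ellipse, style=filled, fillcolor=white];',
    ]
    for name in names:
        lines.append(f'  "{name}";')
    for t, (i, j) in enumerate(summary.transitions):
        occurs = summary.mp_positive[t] > summary.mp_zero[t]
        color = "black" if occurs else "gray70"
        rate = summary.mean_rate[t]
        width = 1.0 if math.isnan(rate) else max(0.5, max_penwidth * rate / rate_max)
        label = f"{summary.mp_zero[t]:.2f}/{summary.mp_positive[t]:.2f}"
        lines.append(
            f'  "{names[i]}" -> "{names[j]}" '
            f'[color={color}, penwidth={width:.2f}, label="{label}"];'
        )
    lines.append("}")
    dot = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(dot)
    return dot


def scores_to_json(scores: Sequence[ModelScore], path=None) -> str:
    payload = [
        {
            "signature": s.signature,
            "frequency": s.frequency,
            "posterior": s.posterior,
            "prior": s.prior,
            "bayes_factor": s.bayes_factor,
            "mean_loglik": s.mean_loglik,
        }
        for s in scores
    ]
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
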