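"""Model signatures, Bell-number model-space combinatorics, Bayes factors,
marginal transition probabilities, and ancestral averaging."""

import itertools
import math

import numpy as np
import pytest

from plumevo.inference import (
    ancestral_average,
    bell_number,
    canonical_signature,
    export_transition_graph,
    marginal_probabilities,
    model_space_size,
    prior_probability,
    score_models,
    top_model_set,
    ModelScore,
    TransitionSummary,
)
from plumevo.rjmcmc import PosteriorSample, SampleRecord, SamplerSettings


def enumerate_structures(K: int):
    """Independent oracle: generate every distinct structure of K transitions
    as a restricted-growth string over {Z, 0, 1, ...}."""
    def extend(prefix, max_class):
        if len(prefix) == K:
            yield tuple(prefix)
            return
        for sym in ["Z"] + [str(c) for c in range(max_class + 2)]:
            new_max = max_class if sym == "Z" or int(sym) <= max_class else int(sym)
            if sym != "Z" and int(sym) > max_class + 1:
                continue
            yield from extend(prefix + [sym], new_max)

    return set(extend([], -1))


def _sample(records, k=4):
    return PosteriorSample(
        k=k, records=records, chain_id=0, settings=SamplerSettings.desk_scale()
    )


def _rec(assignment, values=(), loglik=-10.0, root=(0.25, 0.25, 0.25, 0.25)):
    return SampleRecord(tuple(assignment), tuple(values), loglik, tuple(root))


class TestSignatures:
    def test_all_zero(self):
        assert canonical_signature((-1,) * 12) == ",".join(["Z"] * 12)

    def test_relabeling_invariant(self):
        a = canonical_signature((0, 0, 1, -1))
        b = canonical_signature((1, 1, 0, -1))
        assert a == b == "0,0,1,Z"

    def test_partition_identity(self):
        # classes {a: {1,2}, b: {3}} vs {x: {3}, y: {1,2}} on 12 transitions
        one = [-1] * 12
        one[1] = one[2] = 0
        one[3] = 1
        other = [-1] * 12
        other[3] = 0
        other[1] = other[2] = 1
        assert canonical_signature(tuple(one)) == canonical_signature(tuple(other))


class TestModelSpace:
    def test_bell_numbers(self):
        assert [bell_number(n) for n in range(8)] == [1, 1, 2, 5, 15, 52, 203, 877]

    def test_bell_against_sympy(self):
        from sympy import bell

        for n in range(15):
            assert bell_number(n) == int(bell(n))

    @pytest.mark.parametrize("K", range(6))
    def test_size_matches_exhaustive_enumeration(self, K):
        assert model_space_size(K) == len(enumerate_structures(K))

    def test_size_equals_next_bell_number(self):
        for K in range(13):
            assert model_space_size(K) == bell_number(K + 1)

    def test_k12_value(self):
        assert model_space_size(12) == 27_644_437

    def test_boundaries(self):
        assert model_space_size(0) == 1
        assert model_space_size(2) == 5


class TestPriors:
    def test_k2_uniform(self):
        assert prior_probability("Z,0", 2) == pytest.approx(0.2)

    def test_k3_priors_sum_to_one(self):
        sigs = enumerate_structures(3)
        total = sum(prior_probability(",".join(s), 3) for s in sigs)
        assert total == pytest.approx(1.0)

    def test_k12_prior(self):
        assert prior_probability(",".join(["Z"] * 12), 12) == pytest.approx(1 / 27_644_437)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            prior_probability("Z,Z", 3)


class TestScores:
    def test_single_signature_posterior_one(self):
        sample = _sample([_rec([0] * 12, (0.5,))] * 10)
        (score,) = score_models(sample)
        assert score.posterior == 1.0 and score.frequency == 10

    def test_bayes_factor_arithmetic(self):
        records = [_rec([0] * 12, (0.5,))] * 3 + [_rec([-1] * 12)] * 1997
        scores = {s.signature: s for s in score_models(_sample(records))}
        full = scores[",".join(["0"] * 12)]
        assert full.posterior == pytest.approx(0.0015)
        assert full.bayes_factor == pytest.approx(0.0015 * 27_644_437, rel=1e-12)

    def test_posteriors_sum_to_one(self):
        records = [_rec([0] * 12, (0.5,)), _rec([-1] * 12), _rec([0] * 12, (0.1,))]
        scores = score_models(_sample(records))
        assert sum(s.posterior for s in scores) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_models(_sample([]))


class TestTopModelSet:
    def _scores(self, bfs):
        return [
            ModelScore(f"sig{i}", 1, 0.1, 0.05, bf, -10.0) for i, bf in enumerate(bfs)
        ]

    def test_threshold_is_inclusive(self):
        top = top_model_set(self._scores([5.0, 2.0, 1.9]))
        assert len(top) == 2
        assert [s.bayes_factor for s in top] == [5.0, 2.0]

    def test_empty_set_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert top_model_set(self._scores([1.0, 0.5])) == []

    def test_log_scale_convention(self):
        # 2 ln BF >= 2 corresponds to BF >= e ~ 2.718
        top = top_model_set(self._scores([3.0, 2.5, 2.0]), bf_threshold=2.0, log_scale=True)
        assert [s.bayes_factor for s in top] == [3.0]


class TestMarginalProbabilities:
    def test_counting(self):
        zero = [-1] + [0] * 11
        pos = [0] * 12
        records = [_rec(zero, (0.4,))] * 3 + [_rec(pos, (0.4,))] * 7
        summary = marginal_probabilities(_sample(records), "full_sample")
        assert summary.mp_zero[0] == pytest.approx(0.3)
        assert summary.mp_positive[0] == pytest.approx(0.7)

    def test_full_sample_marginals_sum_to_one(self):
        rng = np.random.default_rng(5)
        records = []
        for _ in range(50):
            assignment = [(-1 if rng.random() < 0.4 else 0) for _ in range(12)]
            values = (0.3,) if any(a == 0 for a in assignment) else ()
            records.append(_rec(assignment, values))
        summary = marginal_probabilities(_sample(records), "full_sample")
        assert np.allclose(summary.mp_zero + summary.mp_positive, 1.0, atol=1e-12)

    def test_top_set_marginals_need_not_sum_to_one(self):
        # two structures at k=2 (prior 1/5 each); the common one has BF 4.5,
        # the rare one BF 0.5 and falls outside the top model set
        common = [SampleRecord((0, 0), (0.5,), -10.0, (0.5, 0.5))] * 9
        rare = [SampleRecord((-1, -1), (), -10.0, (0.5, 0.5))] * 1
        summary = marginal_probabilities(_sample(common + rare, k=2), "top_model_set")
        assert summary.reference_set == "top_model_set"
        total = summary.mp_zero[0] + summary.mp_positive[0]
        assert total == pytest.approx(0.9)

    def test_mean_rate_weighted_over_positive_models(self):
        records = [_rec([0] * 12, (0.2,))] * 2 + [_rec([0] * 12, (0.8,))] * 2 + [
            _rec([-1] * 12)
        ]
        summary = marginal_probabilities(_sample(records), "full_sample")
        assert summary.mean_rate[0] == pytest.approx(0.5)

    def test_interpretation_contract(self):
        # a transition with MP(zero) well below MP(positive) "probably occurs"
        records = [_rec([0] * 12, (0.5,))] * 79 + [_rec([-1] + [0] * 11, (0.5,))] * 9
        summary = marginal_probabilities(_sample(records), "full_sample")
        assert summary.mp_positive[0] > summary.mp_zero[0]


class TestAncestralAverage:
    def test_uniform_samples(self):
        sample = _sample([_rec([-1] * 12)] * 5)
        assert np.allclose(ancestral_average(sample), 0.25)

    def test_indicator_samples(self):
        records = [
            _rec([-1] * 12, root=(0, 1, 0, 0)),
            _rec([-1] * 12, root=(0, 0, 1, 0)),
        ]
        assert np.allclose(ancestral_average(_sample(records)), [0, 0.5, 0.5, 0])


class TestTransitionGraph:
    def _summary(self, mp_zero, mp_positive, mean_rate):
        return TransitionSummary(
            k=4, reference_set="full_sample", total_weight=10,
            mp_zero=np.array(mp_zero), mp_positive=np.array(mp_positive),
            mean_rate=np.array(mean_rate),
        )

    def test_single_positive_transition_single_black_edge(self):
        mp_pos = np.zeros(12)
        mp_pos[0] = 0.9
        rate = np.full(12, np.nan)
        rate[0] = 0.5
        dot = export_transition_graph(self._summary(1 - mp_pos, mp_pos, rate))
        assert dot.count("color=black") == 1
        assert dot.count("color=gray70") == 11

    def test_all_zero_summary_has_no_black_edges(self):
        dot = export_transition_graph(
            self._summary(np.ones(12), np.zeros(12), np.full(12, np.nan))
        )
        assert "color=black" not in dot
        for name in ("uniform", "irregular", "regular", "bimodal"):
            assert f'"{name}"' in dot

    def test_writes_file(self, tmp_path):
        path = tmp_path / "graph.dot"
        export_transition_graph(
            self._summary(np.ones(12), np.zeros(12), np.full(12, np.nan)), path
        )
        assert path.read_text().startswith("digraph")


def test_prior_only_bayes_factors_near_one():
    """On a likelihood-off sample the posterior equals the prior, so every
    structure's BF tends to 1."""
    from plumevo.rjmcmc import run_chain

    settings = SamplerSettings(
        iterations=302_000, burn_in=2_000, sample_every=15, post_thin=1,
        scale_interval=(1e-3, 2.0), seed=13,
    )
    ps = run_chain(None, None, settings, likelihood_on=False, k=2)
    scores = score_models(ps)
    assert len(scores) == 5
    for s in scores:
        assert s.bayes_factor == pytest.approx(1.0, abs=0.15)
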