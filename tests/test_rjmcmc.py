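"""Sampler components: priors, proposals, thinning, determinism, and the
prior-recovery property of the reversible-jump kernel."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

import plumevo as pv
from plumevo.ctmc import RateConfiguration
from plumevo.inference import canonical_signature, model_space_size
from plumevo.rjmcmc import (
    ChainState,
    SamplerSettings,
    propose_rate_update,
    propose_structural_move,
    rate_prior_logdensity,
    run_chain,
)


class TestRatePrior:
    def test_exponential_special_case_at_zero(self):
        s = 0.37
        assert rate_prior_logdensity(0.0, 1.0, s) == pytest.approx(math.log(1 / s))

    @pytest.mark.parametrize("shape,scale", [(1.0, 0.5), (2.0, 1.0), (1.5, 0.2)])
    def test_density_integrates_to_one(self, shape, scale):
        grid = np.linspace(1e-9, shape * scale + 30 * scale, 200_000)
        dens = np.exp([rate_prior_logdensity(v, shape, scale) for v in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_mode_of_shape_two(self):
        grid = np.linspace(1e-6, 10, 100_000)
        dens = [rate_prior_logdensity(v, 2.0, 1.0) for v in grid]
        assert grid[int(np.argmax(dens))] == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            rate_prior_logdensity(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            rate_prior_logdensity(1.0, 1.0, -1.0)


def _state(assignment, values, k=4):
    return ChainState(
        k=k,
        assignment=np.array(assignment, dtype=np.int64),
        values=list(values),
        loglik=0.0,
        root=np.full(k, 1 / k),
        hyper_shape=1.0,
        hyper_scale=0.5,
    )


class TestProposals:
    def test_rate_update_changes_exactly_one_class(self):
        rng = np.random.default_rng(0)
        st = _state([0, 1, -1] + [0] * 9, [0.3, 0.6])
        c, v = propose_rate_update(st, 0.2, rng)
        assert c in (0, 1) and v != st.values[c]

    def test_rate_update_reflection_stays_nonnegative(self):
        rng = np.random.default_rng(1)
        st = _state([0] + [-1] * 11, [0.01])
        for _ in range(100_000):
            _, v = propose_rate_update(st, 0.5, rng)
            assert v >= 0

    def test_from_all_zero_only_unzero_possible(self):
        rng = np.random.default_rng(2)
        st = _state([-1] * 12, [])
        for _ in range(200):
            assign, values, _ = propose_structural_move(st, rng)
            assert sum(1 for a in assign if a != -1) == 1
            assert len(values) == 1

    def test_split_then_merge_restores_signature(self):
        rng = np.random.default_rng(3)
        st = _state([0] * 12, [0.4])
        sig0 = canonical_signature(tuple(st.assignment))
        while True:  # wait for a split (the only dimension-raising move here)
            assign, values, _ = propose_structural_move(st, rng)
            if len(values) == 2:
                break
        st2 = _state(assign, values)
        while True:
            assign2, values2, _ = propose_structural_move(st2, rng)
            if len(values2) == 1 and all(a != -1 for a in assign2):
                break
        assert canonical_signature(tuple(assign2)) == sig0

    def test_tiny_ratedev_accepts_everything(self):
        settings = SamplerSettings(
            iterations=20_000, burn_in=100, sample_every=100, post_thin=1,
            ratedev=1e-9, adapt_every=10**9, rate_move_prob=0.9,
            scale_interval=(1e-3, 2.0), seed=4,
        )
        ps = run_chain(None, None, settings, likelihood_on=False, k=2)
        assert ps.acceptance["rate"] > 0.999


class TestRunChain:
    def test_thinning_arithmetic(self):
        settings = SamplerSettings(
            iterations=105_000, burn_in=50_000, sample_every=1000, post_thin=20,
            scale_interval=(1e-3, 2.0), seed=0,
        )
        ps = run_chain(None, None, settings, likelihood_on=False, k=2)
        assert len(ps) == settings.retained_per_chain == 2

    def test_identical_seeds_identical_samples(self):
        tree = pv.simulate_yule_tree(12, seed=7)
        cfg = pv.get_preset("fig2_hypothesis").config
        mat = pv.simulate_character(tree, cfg, 0, seed=8)
        settings = SamplerSettings(
            iterations=4000, burn_in=500, sample_every=50, post_thin=1, seed=42
        )
        a = run_chain(tree, mat, settings)
        b = run_chain(tree, mat, settings)
        assert a.records == b.records

    def test_retained_loglik_matches_fresh_evaluation(self):
        tree = pv.simulate_yule_tree(15, seed=9)
        cfg = pv.get_preset("fig2_hypothesis").config
        mat = pv.simulate_character(tree, cfg, 0, seed=10)
        settings = SamplerSettings(
            iterations=6000, burn_in=1000, sample_every=100, post_thin=1, seed=1
        )
        ps = run_chain(tree, mat, settings)
        pl = pv.PruningLikelihood(tree, mat)
        for rec in ps.records[:: max(1, len(ps) // 10)]:
            Q = pv.build_rate_matrix(rec.to_configuration(4))
            assert pl.log_likelihood(Q) == pytest.approx(rec.loglik, rel=1e-9)

    def test_prior_only_visits_structures_uniformly(self):
        settings = SamplerSettings(
            iterations=302_000, burn_in=2_000, sample_every=15, post_thin=1,
            scale_interval=(1e-3, 2.0), seed=11,
        )
        ps = run_chain(None, None, settings, likelihood_on=False, k=2)
        counts = Counter(canonical_signature(r.assignment) for r in ps.records)
        assert len(counts) == model_space_size(2) == 5
        obs = np.array(list(counts.values()))
        _, p = chisquare(obs, f_exp=np.full(5, obs.sum() / 5))
        assert p > 0.01

    def test_requires_tree_when_likelihood_on(self):
        with pytest.raises(ValueError, match="required"):
            run_chain(None, None, SamplerSettings.desk_scale(), likelihood_on=True)


def test_structure_posterior_matches_exact_enumeration():
    """End-to-end check of the likelihood-on reversible jump: on a 2-state
    problem with fixed gamma hyperparameters, the exact posterior over the 5
    structures is computable by quadrature (marginal likelihood of each
    structure x the uniform structure prior); the sampled structure
    frequencies must agree."""
    import dendropy
    from scipy import integrate

    from plumevo.characters import CharacterMatrix, SpeciesRecord
    from plumevo.ctmc import PruningLikelihood

    newick = "((A:0.6,B:0.6):0.7,(C:1.0,D:0.3):0.3,E:1.3);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    states = {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}
    mat = CharacterMatrix([SpeciesRecord(t, state=s) for t, s in states.items()])
    pl = PruningLikelihood(tree, mat, k=2)
    shape, scale = 1.0, 0.8

    def lik(q01, q10):
        Q = np.array([[-q01, q01], [q10, -q10]])
        return math.exp(pl.log_likelihood(Q))

    def g(v):
        return math.exp(rate_prior_logdensity(v, shape, scale))

    hi = 30 * scale
    m = {
        "Z,Z": lik(0, 0),
        "0,Z": integrate.quad(lambda v: lik(v, 0) * g(v), 0, hi)[0],
        "Z,0": integrate.quad(lambda v: lik(0, v) * g(v), 0, hi)[0],
        "0,0": integrate.quad(lambda v: lik(v, v) * g(v), 0, hi)[0],
        "0,1": integrate.dblquad(
            lambda b, a: lik(a, b) * g(a) * g(b), 0, hi, 0, hi, epsabs=1e-12
        )[0],
    }
    total = sum(m.values())
    exact = {sig: v / total for sig, v in m.items()}

    settings = SamplerSettings(
        iterations=802_000, burn_in=2_000, sample_every=8, post_thin=1,
        shape_interval=(shape, shape), scale_interval=(scale, scale), seed=17,
    )
    ps = run_chain(tree, mat, settings, likelihood_on=True, k=2)
    counts = Counter(canonical_signature(r.assignment) for r in ps.records)
    for sig, p_exact in exact.items():
        p_chain = counts.get(sig, 0) / len(ps)
        assert p_chain == pytest.approx(p_exact, abs=0.02), (sig, p_chain, p_exact)


def test_samples_tsv_round_trip(tmp_path):
    settings = SamplerSettings(
        iterations=5000, burn_in=500, sample_every=50, post_thin=2,
        scale_interval=(1e-3, 2.0), seed=3,
    )
    ps = run_chain(None, None, settings, likelihood_on=False, k=4, chain_id=2)
    path = tmp_path / "samples.tsv"
    pv.rjmcmc.write_samples_tsv([ps], path)
    back = pv.rjmcmc.read_samples_tsv(path, k=4)
    assert len(back) == 1 and back[0].chain_id == 2
    got = back[0].records
    assert len(got) == len(ps.records)
    for a, b in zip(got, ps.records):
        assert a.assignment == b.assignment
        assert a.values == pytest.approx(b.values)


def test_malformed_samples_tsv_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("chain\tindex\tassignment\tvalues\tlogL\troot\n0\t0\toops\n")
    with pytest.raises(ValueError, match="bad.tsv:2"):
        pv.rjmcmc.read_samples_tsv(path)


def test_fitch_parsimony_counts():
    import dendropy
    from plumevo.rjmcmc import fitch_parsimony_changes

    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    assert fitch_parsimony_changes(tree, {"A": 0, "B": 0, "C": 0, "D": 0}) == 0
    assert fitch_parsimony_changes(tree, {"A": 0, "B": 1, "C": 0, "D": 0}) == 1
    assert fitch_parsimony_changes(tree, {"A": 0, "B": 1, "C": 2, "D": 3}) == 3
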