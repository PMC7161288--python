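"""Conditional inference engine: ESF tables, conditional probabilities,
moments, sampling, and their exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from gllrasch.cml import ConditionalModel, GroupedData, log_convolve, model_dof

from conftest import enumerate_logweights


class TestESF:
    def test_two_dichotomous_items_closed_form(self):
        cm = ConditionalModel(["a", "b"], 1)
        theta = np.array([0.4, -0.9])
        tabs = cm.tables(theta)
        e1, e2 = np.exp(theta)
        gam = np.exp(tabs.esf())
        assert gam[0] == pytest.approx(1.0)
        assert gam[1] == pytest.approx(e1 + e2, rel=1e-12)
        assert gam[2] == pytest.approx(e1 * e2, rel=1e-12)

    def test_single_item_degenerate_case(self):
        cm = ConditionalModel(["a", "b"], {"a": 4, "b": 1})
        theta = np.zeros(cm.layout.n_params)
        theta[:4] = [0.3, -0.2, 0.8, -1.1]
        # single-item ESF of 'a' via its component table
        tabs = cm.tables(theta)
        zeta = tabs.zeta[(0, 0)]
        alpha = cm.layout.alpha_array(theta, "a")
        assert np.allclose(zeta, alpha)

    def test_three_by_three_matches_enumeration(self, small_model):
        cm, theta = small_model
        patterns, logws = enumerate_logweights(cm, theta)
        scores = patterns.sum(axis=1)
        expected = np.array([logsumexp(logws[scores == r]) for r in range(7)])
        assert np.allclose(tabs_esf := cm.tables(theta).esf(), expected,
                           atol=1e-12)
        assert tabs_esf[0] == 0.0

    def test_log_convolve_against_direct_product(self, rng):
        la = rng.normal(0, 2, 5)
        lb = rng.normal(0, 2, 3)
        out = log_convolve(la, lb)
        direct = np.full(7, -np.inf)
        for i, a in enumerate(la):
            for j, b in enumerate(lb):
                direct[i + j] = np.logaddexp(direct[i + j], a + b)
        assert np.allclose(out, direct, atol=1e-12)


class TestConditionalProbabilities:
    def test_normalisation_within_each_score_group(self, small_model):
        cm, theta = small_model
        tabs = cm.tables(theta)
        for r in range(7):
            total = sum(
                np.exp(tabs.pattern_logprob(pat, r))
                for pat in itertools.product(range(3), repeat=3)
                if sum(pat) == r)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_extreme_scores_are_degenerate(self, small_model):
        cm, theta = small_model
        tabs = cm.tables(theta)
        assert tabs.pattern_logprob((0, 0, 0), 0) == pytest.approx(0.0)
        assert tabs.pattern_logprob((2, 2, 2), 6) == pytest.approx(0.0)

    def test_score_mismatch_rejected(self, small_model):
        cm, theta = small_model
        with pytest.raises(ValueError):
            cm.tables(theta).pattern_logprob((1, 0, 0), 2)

    def test_matches_enumeration_oracle(self, small_model):
        cm, theta = small_model
        tabs = cm.tables(theta)
        patterns, logws = enumerate_logweights(cm, theta)
        scores = patterns.sum(axis=1)
        for pat, lw, r in zip(patterns, logws, scores):
            denom = logsumexp(logws[scores == r])
            assert tabs.pattern_logprob(tuple(pat), r) == \
                pytest.approx(lw - denom, abs=1e-10)


class TestGLLRMConditionals:
    def test_reduces_to_pcm_when_interactions_zero(self, small_model):
        cm, theta = small_model
        cmg = ConditionalModel(cm.items, 2, ld_pairs=[("a", "b")],
                               dif_terms=[("c", "g")],
                               cov_levels={"g": ["x", "y"]})
        thg = np.zeros(cmg.layout.n_params)
        for k, nm in enumerate(cm.layout.names):
            thg[cmg.layout.index[nm]] = theta[k]
        t_p = cm.tables(theta)
        t_g = cmg.tables(thg)
        for prof in (0, 1):
            for pat in itertools.product(range(3), repeat=3):
                r = sum(pat)
                assert t_g.pattern_logprob(pat, r, prof) == \
                    pytest.approx(t_p.pattern_logprob(pat, r), abs=1e-10)

    @pytest.mark.parametrize("profile", [0, 1])
    def test_ld_and_dif_match_enumeration(self, small_gllrm, profile):
        cm, theta = small_gllrm
        tabs = cm.tables(theta)
        patterns, logws = enumerate_logweights(cm, theta, profile)
        scores = patterns.sum(axis=1)
        for pat, lw, r in zip(patterns, logws, scores):
            denom = logsumexp(logws[scores == r])
            assert tabs.pattern_logprob(tuple(pat), r, profile) == \
                pytest.approx(lw - denom, abs=1e-10)

    def test_normalisation_per_score_and_profile(self, small_gllrm):
        cm, theta = small_gllrm
        tabs = cm.tables(theta)
        for prof in range(2):
            for r in range(7):
                total = sum(
                    np.exp(tabs.pattern_logprob(pat, r, prof))
                    for pat in itertools.product(range(3), repeat=3)
                    if sum(pat) == r)
                assert total == pytest.approx(1.0, abs=1e-10)


class TestConditionalMoments:
    def test_extreme_scores_have_deterministic_moments(self, small_gllrm):
        cm, theta = small_gllrm
        E, V = cm.tables(theta).item_moments(1)
        for it in cm.items:
            assert E[it][0] == pytest.approx(0.0, abs=1e-12)
            assert V[it][0] == pytest.approx(0.0, abs=1e-12)
            assert E[it][6] == pytest.approx(2.0, abs=1e-10)
            assert V[it][6] == pytest.approx(0.0, abs=1e-10)

    def test_moments_match_enumeration(self, small_gllrm):
        cm, theta = small_gllrm
        tabs = cm.tables(theta)
        E, V = tabs.item_moments(0)
        patterns, logws = enumerate_logweights(cm, theta, 0)
        scores = patterns.sum(axis=1)
        for r in range(7):
            sel = scores == r
            w = np.exp(logws[sel] - logsumexp(logws[sel]))
            for k, it in enumerate(cm.items):
                y = patterns[sel, k]
                assert E[it][r] == pytest.approx(w @ y, abs=1e-10)
                assert V[it][r] == pytest.approx(
                    w @ y ** 2 - (w @ y) ** 2, abs=1e-10)


class TestGaugeAndSufficientStats:
    def test_probabilities_invariant_to_gauge_shift(self, small_model):
        """Adding c*y to every item's alpha leaves conditional probabilities
        unchanged (the identification re-centres the same orbit)."""
        cm, theta = small_model
        shifted = theta.copy()
        for k, nm in enumerate(cm.layout.names):
            shifted[k] += 0.37 * nm[2]
        t1, t2 = cm.tables(theta), cm.tables(shifted)
        for pat in itertools.product(range(3), repeat=3):
            r = sum(pat)
            assert t1.pattern_logprob(pat, r) == \
                pytest.approx(t2.pattern_logprob(pat, r), abs=1e-10)
        renorm = cm.layout.normalize_gauge(shifted)
        assert np.allclose(renorm, theta, atol=1e-10)

    def test_score_equation_identity_at_solution(self, rng):
        """At the CML solution the expected item margins reproduce the
        observed margins: sum_r n_r E[Y_i|R=r] = observed item total."""
        from gllrasch.model import PartialCreditModel
        from conftest import make_data

        cm = ConditionalModel([f"i{j}" for j in range(4)], 3)
        gen = cm.layout.normalize_gauge(rng.normal(0, 0.6, cm.layout.n_params))
        resp = cm.tables(gen).sample_given_theta(
            rng, rng.normal(0, 1.2, 800), 0)
        res = PartialCreditModel(make_data(resp, m=3)).fit(se=False)
        g = res.model.grouped
        E, _ = res.tables().item_moments(0)
        n_r = g.n_by_score[0]
        used = g.nonextreme
        for k, it in enumerate(res.cmodel.items):
            expected = n_r @ E[it]
            observed = resp[used, k].sum()
            assert expected == pytest.approx(observed, rel=1e-6)


class TestSampling:
    def test_conditional_sampler_preserves_scores_and_frequencies(self,
                                                                  small_gllrm):
        cm, theta = small_gllrm
        tabs = cm.tables(theta)
        r = np.random.default_rng(3)
        scores = np.repeat(3, 40_000)
        draws = tabs.sample_conditional(r, scores, profile_idx=1)
        assert (draws.sum(axis=1) == 3).all()
        # empirical pattern frequencies match conditional probabilities
        pats = [p for p in itertools.product(range(3), repeat=3)
                if sum(p) == 3]
        for pat in pats:
            p_true = np.exp(tabs.pattern_logprob(pat, 3, 1))
            p_emp = np.mean((draws == pat).all(axis=1))
            assert p_emp == pytest.approx(p_true, abs=0.01)

    def test_theta_sampler_matches_score_distribution(self, small_model):
        cm, theta = small_model
        tabs = cm.tables(theta)
        r = np.random.default_rng(4)
        th = np.full(60_000, 0.5)
        draws = tabs.sample_given_theta(r, th, 0)
        pmf = np.exp(tabs.score_logpmf_given_theta(0.5)[0])
        emp = np.bincount(draws.sum(axis=1), minlength=7) / len(th)
        assert np.abs(emp - pmf).max() < 0.01


class TestModelDof:
    @pytest.mark.parametrize("k,m,expected", [(14, 4, 55), (7, 4, 27)])
    def test_pure_rm_free_parameter_count(self, k, m, expected):
        cm = ConditionalModel([f"i{j}" for j in range(k)], m)
        assert model_dof(cm) == expected

    def test_ld_pair_adds_full_corner_constrained_grid(self):
        base = ConditionalModel([f"i{j}" for j in range(5)], 4)
        with_ld = ConditionalModel([f"i{j}" for j in range(5)], 4,
                                   ld_pairs=[("i0", "i1")])
        assert model_dof(with_ld) - model_dof(base) == 16

    def test_dif_term_adds_categories_times_levels(self):
        base = ConditionalModel([f"i{j}" for j in range(5)], 4)
        with_dif = ConditionalModel(
            [f"i{j}" for j in range(5)], 4, dif_terms=[("i0", "g")],
            cov_levels={"g": ["a", "b", "c"]})
        assert model_dof(with_dif) - model_dof(base) == 4 * 2


class TestStructureValidation:
    def test_duplicate_ld_pair_rejected(self):
        with pytest.raises(ValueError):
            ConditionalModel(["a", "b"], 2, ld_pairs=[("a", "b"), ("b", "a")])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            ConditionalModel(["a", "b"], 2, ld_pairs=[("a", "a")])

    def test_dif_needs_cov_levels(self):
        with pytest.raises(ValueError):
            ConditionalModel(["a", "b"], 2, dif_terms=[("a", "g")])

    def test_overlapping_ld_pairs_merge_into_one_component(self):
        cm = ConditionalModel(["a", "b", "c", "d"], 2,
                              ld_pairs=[("a", "b"), ("b", "c")])
        sizes = sorted(len(c.items) for c in cm.components)
        assert sizes == [1, 3]
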