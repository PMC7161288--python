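"""Person-side quantities: WML, information, targeting, reliability,
separation, DIF score conversion, rank correlations."""

import numpy as np
import pandas as pd
import pytest

from gllrasch.cml import ConditionalModel
from gllrasch.model import GLLRM, PartialCreditModel
from gllrasch.scoring import (PersonDist, adjusted_group_comparison,
                              cronbach_alpha, dif_conversion_table,
                              estimate_person_dist, expected_score,
                              kendall_tau, mc_reliability, person_separation,
                              target_index, wml_table, wml_theta)
from gllrasch.scoring import test_information as information
from gllrasch.simulate import (GENERIC_DIF_SCALAR_03, null_pcm_config,
                               simulate_dataset)

from conftest import make_data


@pytest.fixture(scope="module")
def pcm_results():
    cfg = null_pcm_config(n=3000, k=5)
    data, _ = simulate_dataset(cfg, seed=33)
    return PartialCreditModel(data).fit(se=False)


@pytest.fixture(scope="module")
def dif_results():
    cfg = null_pcm_config(n=8000, k=5)
    cfg.dif_terms = [("i1", "sex", GENERIC_DIF_SCALAR_03)]
    data, gt = simulate_dataset(cfg, seed=34)
    res = GLLRM(data, dif=[("i1", "sex")]).fit(se=False)
    return data, gt, res


class TestWML:
    def test_symmetric_instrument_centre_score_maps_to_zero(self):
        cm = ConditionalModel([f"i{j}" for j in range(4)], 2)
        res_like = _results_from(cm, np.zeros(cm.layout.n_params))
        th, se = wml_theta(res_like, 4)     # half of R_max = 8
        assert th == pytest.approx(0.0, abs=1e-6)
        assert se > 0

    def test_strictly_increasing_in_score_and_finite_extremes(self,
                                                              pcm_results):
        tab = wml_table(pcm_results)
        assert (np.diff(tab["theta"]) > 0).all()
        assert np.isfinite(tab["theta"]).all()

    def test_matches_fine_grid_maximisation(self, pcm_results):
        tabs = pcm_results.tables()
        grid = np.linspace(-8, 8, 16001)
        lp = tabs.score_logpmf_given_theta(grid)
        _, info = tabs.score_moments_given_theta(grid)
        for r in (3, 9, 15):
            obj = lp[:, r] + 0.5 * np.log(info)
            th_grid = grid[obj.argmax()]
            th, _ = wml_theta(pcm_results, r)
            assert th == pytest.approx(th_grid, abs=2e-3)

    def test_out_of_range_score_rejected(self, pcm_results):
        with pytest.raises(ValueError):
            wml_theta(pcm_results, 999)


def _results_from(cm, theta):
    """Minimal Results-like wrapper for scoring functions on a bare model."""
    from gllrasch.model import GLLRMResults

    class _Stub:
        pass

    stub = _Stub()
    stub.cmodel = cm
    res = GLLRMResults.__new__(GLLRMResults)
    res.cmodel = cm
    res.theta_full = theta
    res._tables = cm.tables(theta)
    return res


class TestInformation:
    def test_vanishes_in_the_tails(self, pcm_results):
        assert information(pcm_results, -30) < 1e-6
        assert information(pcm_results, 30) < 1e-6
        assert information(pcm_results, 0) > 0.5

    def test_equals_negative_second_derivative(self, pcm_results):
        tabs = pcm_results.tables()
        h = 1e-4
        r = 8
        lp = lambda t: tabs.score_logpmf_given_theta(t)[0, r]
        num = -(lp(0.3 + h) - 2 * lp(0.3) + lp(0.3 - h)) / h ** 2
        assert information(pcm_results, 0.3) == pytest.approx(num, rel=1e-4)

    def test_composite_ld_conveys_less_information_on_average(self):
        """A materially dependent pair carries less population-averaged
        information than the same two items would independently.  (The
        interaction warps the information *function*, so the comparison is
        over the trait distribution, not pointwise.)"""
        cm0 = ConditionalModel(["a", "b"], 4)
        cm1 = ConditionalModel(["a", "b"], 4, ld_pairs=[("a", "b")])
        theta0 = np.zeros(cm0.layout.n_params)
        theta1 = np.zeros(cm1.layout.n_params)
        for k, nm in enumerate(cm1.layout.names):
            if nm[0] == "lambda":
                theta1[k] = 0.4 * nm[3] * nm[4]
        r0 = _results_from(cm0, theta0)
        r1 = _results_from(cm1, theta1)
        nodes, w = np.polynomial.hermite_e.hermegauss(41)
        w = w / w.sum()
        mean0 = float(w @ information(r0, nodes))
        mean1 = float(w @ information(r1, nodes))
        assert mean1 < mean0


class TestTargeting:
    def test_degenerate_distribution_at_maximum_gives_index_one(self,
                                                                pcm_results):
        star = target_index(pcm_results,
                            PersonDist(0.0, 1.0))["theta_star"]
        ti = target_index(pcm_results, PersonDist(star, 1e-6))
        assert ti["index"] == pytest.approx(1.0, abs=1e-6)

    def test_far_off_target_population_has_index_near_zero(self, pcm_results):
        ti = target_index(pcm_results, PersonDist(-12.0, 0.3))
        assert ti["index"] < 0.01

    def test_index_always_in_unit_interval(self, pcm_results):
        for mu in (-3, -1, 0, 2):
            ti = target_index(pcm_results, PersonDist(mu, 1.0))
            assert 0 < ti["index"] <= 1


class TestReliability:
    def test_cronbach_hand_computed_matrix(self):
        """3 items x 6 persons, worked through the definitional formula."""
        mat = np.array([[0, 1, 1], [1, 1, 2], [2, 2, 2],
                        [3, 2, 3], [4, 3, 3], [4, 4, 4]])
        item_vars = mat.var(axis=0, ddof=1)
        total_var = mat.sum(axis=1).var(ddof=1)
        expected = 3 / 2 * (1 - item_vars.sum() / total_var)
        assert cronbach_alpha(make_data(mat)) == pytest.approx(expected)

    def test_parallel_items_drive_alpha_to_one(self, rng):
        base = rng.integers(0, 5, size=(500, 1))
        mat = np.repeat(base, 8, axis=1)
        assert cronbach_alpha(make_data(mat)) == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self, rng):
        mat = rng.integers(0, 5, size=(4000, 6))
        assert abs(cronbach_alpha(make_data(mat))) < 0.05

    def test_mc_reliability_is_seed_deterministic(self, pcm_results):
        d = PersonDist(0.0, 1.2)
        a = mc_reliability(pcm_results, d, 20_000, seed=5)
        b = mc_reliability(pcm_results, d, 20_000, seed=5)
        assert a == b
        with pytest.warns(UserWarning):
            mc_reliability(pcm_results, d, 500, seed=5)

    def test_agrees_with_independent_pair_simulation(self, pcm_results):
        """Cross-check against a brute-force simulation that draws full
        response patterns and computes Var(E[R|theta])/Var(R) empirically."""
        d = PersonDist(0.0, 1.2)
        rel = mc_reliability(pcm_results, d, 200_000, seed=6)
        r = np.random.default_rng(17)
        th = d.mean + d.sd * r.standard_normal(150_000)
        tabs = pcm_results.tables()
        resp = tabs.sample_given_theta(r, th, 0)
        scores = resp.sum(axis=1)
        e, _ = tabs.score_moments_given_theta(th)
        rel_brute = e.var() / scores.var()
        assert rel == pytest.approx(rel_brute, abs=0.01)


class TestPersonSeparation:
    def test_degenerate_trait_distribution_gives_half(self, pcm_results):
        p = person_separation(pcm_results, PersonDist(0.0, 1e-9),
                              30_000, seed=7)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_highly_informative_instrument_approaches_one(self):
        cm = ConditionalModel([f"i{j}" for j in range(30)], 4)
        res = _results_from(cm, np.zeros(cm.layout.n_params))
        p = person_separation(res, PersonDist(0.0, 2.0), 30_000, seed=8)
        assert p > 0.95

    def test_matches_brute_force_pairwise_simulation(self, pcm_results):
        d = PersonDist(0.0, 1.2)
        p = person_separation(pcm_results, d, 150_000, seed=9)
        r = np.random.default_rng(19)
        t1 = d.mean + d.sd * r.standard_normal(100_000)
        t2 = d.mean + d.sd * r.standard_normal(100_000)
        tabs = pcm_results.tables()
        r1 = tabs.sample_given_theta(r, t1, 0).sum(axis=1)
        r2 = tabs.sample_given_theta(r, t2, 0).sum(axis=1)
        agree = np.where(r1 == r2, 0.5,
                         (np.sign(r1 - r2) == np.sign(t1 - t2)))
        assert p == pytest.approx(agree.mean(), abs=0.01)


class TestConversionTable:
    def test_reference_profile_is_identity_and_monotone(self, dif_results):
        data, gt, res = dif_results
        tab = dif_conversion_table(res)
        ref = tab[tab["profile"] == 0]
        assert (ref["adjusted"] == ref["score"]).all()
        for _, grp in tab.groupby("profile"):
            assert (np.diff(grp["adjusted"]) >= -1e-9).all()

    def test_floor_maps_near_floor(self, dif_results):
        data, gt, res = dif_results
        tab = dif_conversion_table(res)
        assert (tab[tab["score"] == 0]["adjusted"] < 2.0).all()

    def test_requires_dif_terms(self, pcm_results):
        with pytest.raises(ValueError):
            dif_conversion_table(pcm_results)

    def test_adjustment_removes_dif_bias(self, dif_results):
        """Equal latent means with DIF: the observed sex difference is
        material, the adjusted difference is near zero."""
        data, gt, res = dif_results
        tab = dif_conversion_table(res)
        cmp = adjusted_group_comparison(data, res, tab, "sex")
        assert abs(cmp["observed_diff"].iloc[0]) > 0.3
        assert abs(cmp["adjusted_diff"].iloc[0]) < \
            0.35 * abs(cmp["observed_diff"].iloc[0])

    def test_identity_table_gives_zero_bias(self, dif_results):
        data, gt, res = dif_results
        tab = dif_conversion_table(res)
        ident = tab.copy()
        ident["adjusted"] = ident["score"].astype(float)
        cmp = adjusted_group_comparison(data, res, ident, "sex")
        assert np.allclose(cmp["bias"], 0.0)


class TestKendallTau:
    def test_perfect_and_null_association(self, rng):
        x = np.arange(50)
        tau, p = kendall_tau(x, x)
        assert tau == pytest.approx(1.0)
        a = rng.integers(0, 5, 2000)
        b = rng.integers(0, 5, 2000)
        tau0, _ = kendall_tau(a, b)
        assert abs(tau0) < 0.05

    def test_hand_enumerated_five_pairs(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        # 8 concordant, 2 discordant, no ties: tau = (8-2)/10
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestPersonDistEstimate:
    def test_recovers_generating_normal(self):
        cfg = null_pcm_config(n=20_000, k=5, sd=1.2)
        data, gt = simulate_dataset(cfg, seed=4)
        res = PartialCreditModel(data).fit(se=False)
        d = estimate_person_dist(res)
        assert d.mean == pytest.approx(0.0, abs=0.06)
        assert d.sd == pytest.approx(1.2, abs=0.06)

    def test_wml_moment_method_available(self, pcm_results):
        d = estimate_person_dist(pcm_results, method="wml")
        assert d.sd > 0
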