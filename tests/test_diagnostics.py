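"""Diagnostics: CLR, item fit, Kelderman screening, gamma coefficients,
BH adjustment, ICC tables, unidimensionality."""

import numpy as np
import pandas as pd
import pytest

from gllrasch.cml import ConditionalModel
from gllrasch.diagnostics import (bh_adjust, clr_test, conditional_item_fit,
                                  gamma_coefficient, icc_table, kelderman_lr,
                                  partial_gamma_dif, partial_gamma_ld,
                                  unidimensionality_test)
from gllrasch.model import GLLRM, PartialCreditModel
from gllrasch.simulate import (ItemSim, SimConfig, _alpha_from_location,
                               null_pcm_config, simulate_dataset,
                               DEFAULT_COVARIATES, GENERIC_LD_SCALAR_02,
                               GENERIC_DIF_SCALAR_03)

from conftest import make_data


def brute_force_gamma(x, y):
    """O(n^2) pair-count oracle for Goodman-Kruskal gamma."""
    C = D = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                C += 1
            elif s < 0:
                D += 1
    return (C - D) / (C + D) if C + D else np.nan


class TestGammaCoefficient:
    def test_perfect_agreement_and_reversal(self):
        x = np.array([0, 1, 2, 3, 2, 1])
        assert gamma_coefficient(x, x).gamma == pytest.approx(1.0)
        assert gamma_coefficient(x, -x).gamma == pytest.approx(-1.0)

    def test_two_by_two_hand_count(self):
        """Table [[10,5],[5,10]]: C=100, D=25, gamma=(100-25)/125=0.6."""
        x = [0] * 15 + [1] * 15
        y = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
        est = gamma_coefficient(x, y)
        assert est.gamma == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_pair_count(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, 150)
        y = np.clip(x + r.integers(-2, 3, 150), 0, 4)
        est = gamma_coefficient(x, y)
        assert est.gamma == pytest.approx(brute_force_gamma(x, y), abs=1e-12)

    def test_degenerate_input_flagged(self):
        est = gamma_coefficient([1, 1, 1], [0, 1, 2])
        assert not est.defined


@pytest.fixture(scope="module")
def ld_data():
    cfg = null_pcm_config(n=30_000, k=5)
    cfg.ld_terms = [("i0", "i1", GENERIC_LD_SCALAR_02)]
    data, _ = simulate_dataset(cfg, seed=13)
    return data


class TestPartialGamma:
    def test_null_items_have_near_zero_partial_gamma(self):
        cfg = null_pcm_config(n=6000, k=5)
        data, _ = simulate_dataset(cfg, seed=14)
        est = partial_gamma_ld(data, "i2", "i3", [f"i{j}" for j in range(5)])
        assert abs(est.gamma) < 2.5 * est.se + 0.02

    def test_calibrated_ld_pair_recovered(self, ld_data):
        est = partial_gamma_ld(ld_data, "i0", "i1",
                               [f"i{j}" for j in range(5)])
        assert est.gamma == pytest.approx(0.2, abs=0.05)
        assert set(est.directional) == {"given_rest_i", "given_rest_j"}

    def test_item_with_itself_rejected(self, ld_data):
        with pytest.raises(ValueError):
            partial_gamma_ld(ld_data, "i0", "i0", [f"i{j}" for j in range(5)])

    def test_calibrated_dif_recovered(self):
        cfg = null_pcm_config(n=30_000, k=5)
        cfg.dif_terms = [("i1", "sex", GENERIC_DIF_SCALAR_03)]
        data, _ = simulate_dataset(cfg, seed=15)
        est = partial_gamma_dif(data, "i1", "sex",
                                [f"i{j}" for j in range(5)])
        assert est.gamma == pytest.approx(0.3, abs=0.05)

    def test_single_level_covariate_rejected(self, ld_data):
        data = ld_data
        cov = data.covariates.copy()
        cov["const"] = "only"
        data2 = make_data(data.matrix(), covariates=cov,
                          covariate_levels={**data.covariate_levels,
                                            "const": ["only"]})
        with pytest.raises(ValueError):
            partial_gamma_dif(data2, "i0", "const",
                              [f"i{j}" for j in range(5)])

    def test_sign_flips_with_covariate_relabeling(self):
        cfg = null_pcm_config(n=4000, k=5)
        cfg.dif_terms = [("i1", "sex", GENERIC_DIF_SCALAR_03)]
        data, _ = simulate_dataset(cfg, seed=16)
        est = partial_gamma_dif(data, "i1", "sex",
                                [f"i{j}" for j in range(5)])
        flipped = make_data(data.matrix(), covariates=data.covariates,
                            covariate_levels={"sex": ["Female", "Male"],
                                              "education": data.covariate_levels["education"]})
        est2 = partial_gamma_dif(flipped, "i1", "sex",
                                 [f"i{j}" for j in range(5)])
        assert est2.gamma == pytest.approx(-est.gamma, abs=1e-12)


class TestBHAdjust:
    def test_single_and_tied_pvalues_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_worked_step_up(self):
        """(0.01, 0.04, 0.03) -> (0.03, 0.04, 0.04) in input order."""
        adj = bh_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])


class TestCLR:
    def test_identical_half_samples_give_zero(self, rng):
        cm = ConditionalModel([f"i{j}" for j in range(4)], 3)
        gen = cm.layout.normalize_gauge(rng.normal(0, 0.5, cm.layout.n_params))
        resp = cm.tables(gen).sample_given_theta(rng, rng.normal(0, 1, 400), 0)
        doubled = np.vstack([resp, resp])
        cov = pd.DataFrame({"g": ["x"] * 400 + ["y"] * 400})
        data = make_data(doubled, m=3, covariates=cov,
                         covariate_levels={"g": ["x", "y"]})
        res = PartialCreditModel(data).fit(se=False)
        t = clr_test(res, "g")
        assert t.statistic == pytest.approx(0.0, abs=1e-6)
        assert t.df == res.df_model

    def test_score_split_dof_arithmetic(self):
        cfg = null_pcm_config(n=4000, k=5)
        data, _ = simulate_dataset(cfg, seed=17)
        res = PartialCreditModel(data).fit(se=False)
        t = clr_test(res, "score")
        # both halves observe all categories here, so df = pooled df
        assert t.df == res.df_model == 19
        assert t.statistic >= 0

    def test_empty_group_rejected(self, rng):
        cm = ConditionalModel(["a", "b"], 2)
        resp = cm.tables(np.zeros(4)).sample_given_theta(
            rng, rng.normal(0, 1, 100), 0)
        cov = pd.DataFrame({"g": ["x"] * 100})
        data = make_data(resp, m=2, items=["a", "b"], covariates=cov,
                         covariate_levels={"g": ["x", "y"]})
        res = PartialCreditModel(data).fit(se=False)
        with pytest.raises(ValueError):
            clr_test(res, "g")


class TestKelderman:
    def test_included_term_rejected_as_candidate(self):
        cfg = null_pcm_config(n=800, k=4)
        cfg.ld_terms = [("i0", "i1", 0.2)]
        data, _ = simulate_dataset(cfg, seed=18)
        res = GLLRM(data, ld=[("i0", "i1")]).fit(se=False)
        with pytest.raises(ValueError):
            kelderman_lr(res, ("ld", "i0", "i1"))
        with pytest.raises(ValueError):
            kelderman_lr(res, ("dif", "zzz", "sex"))

    def test_df_counts_added_cells(self):
        cfg = null_pcm_config(n=2500, k=4)
        data, _ = simulate_dataset(cfg, seed=19)
        res = PartialCreditModel(data).fit(se=False)
        t_ld = kelderman_lr(res, ("ld", "i0", "i1"))
        assert t_ld.df == 16 and t_ld.statistic >= 0
        t_dif = kelderman_lr(res, ("dif", "i0", "sex"))
        assert t_dif.df == 4


class TestItemFit:
    def test_null_calibration_and_determinism(self):
        cfg = null_pcm_config(n=2000, k=5)
        data, _ = simulate_dataset(cfg, seed=20)
        res = PartialCreditModel(data).fit(se=False)
        tab = conditional_item_fit(res, n_boot=150, seed=2)
        assert np.abs(tab["outfit"] - 1).max() < 0.1
        assert np.abs(tab["infit"] - 1).max() < 0.1
        tab2 = conditional_item_fit(res, n_boot=150, seed=2)
        pd.testing.assert_frame_equal(tab, tab2)

    def test_duplicated_item_shows_over_discrimination(self, rng):
        """A verbatim copy of an item (extreme LD) drives the pair's fit
        statistics below 1."""
        cm = ConditionalModel([f"i{j}" for j in range(4)], 3)
        gen = cm.layout.normalize_gauge(rng.normal(0, 0.5, cm.layout.n_params))
        resp = cm.tables(gen).sample_given_theta(
            rng, rng.normal(0, 1.2, 2500), 0)
        resp = np.column_stack([resp, resp[:, 0]])
        res = PartialCreditModel(make_data(resp, m=3)).fit(se=False)
        tab = conditional_item_fit(res, n_boot=100, seed=3).set_index("item")
        assert tab.loc["i0", "outfit"] < 1
        assert tab.loc["i4", "outfit"] < 1
        assert tab.loc["i0", "outfit_p"] < 0.05


class TestICCTable:
    def test_conforming_item_points_inside_band(self):
        cfg = null_pcm_config(n=4000, k=5)
        data, _ = simulate_dataset(cfg, seed=22)
        res = PartialCreditModel(data).fit(se=False)
        tab = icc_table(res, "i2")
        big = tab[tab["n"] >= 30]
        inside = ((big["observed"] >= big["lower"]) &
                  (big["observed"] <= big["upper"])).mean()
        assert inside >= 0.85
        assert (tab["n"] > 0).all()

    def test_under_discriminating_item_flatter_than_expected(self):
        cfg = null_pcm_config(n=4000, k=5)
        cfg.items[2] = ItemSim("i2", "t", cfg.items[2].alpha,
                               discrimination=0.45)
        data, _ = simulate_dataset(cfg, seed=23)
        res = PartialCreditModel(data).fit(se=False)
        tab = icc_table(res, "i2")
        big = tab[tab["n"] >= 50]
        obs_slope = np.polyfit(big["score"], big["observed"], 1)[0]
        exp_slope = np.polyfit(big["score"], big["expected"], 1)[0]
        assert obs_slope < exp_slope


class TestUnidimensionality:
    def test_overlapping_item_sets_rejected(self):
        cfg = null_pcm_config(n=500, k=5)
        data, _ = simulate_dataset(cfg, seed=24)
        ra = PartialCreditModel(data, items=["i0", "i1", "i2"]).fit(se=False)
        rb = PartialCreditModel(data, items=["i2", "i3", "i4"]).fit(se=False)
        with pytest.raises(ValueError):
            unidimensionality_test(ra, rb, n_sim=1000)
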