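"""Downstream associations: correlations, p53, survival, NSAID response."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import parainflam as pf
from parainflam.datatypes import ExpressionMatrix


@pytest.fixture(scope="module")
def scored_cohort():
    """Adjusted, scored and classified synthetic cohort shared here."""
    cfg = pf.SimConfig(seed=41, n_genes=500, n_tumors_per_tissue=300,
                       n_normals_per_tissue=80, n_inflammatory_genes=100)
    normals, _ = pf.simulate_reference_normals(cfg)
    expr, ann, truth = pf.simulate_tumor_cohort(cfg)
    model = pf.fit_infiltration_slopes(normals)
    adj = pf.adjust_expression(expr, model).matrix
    scores = pf.score_cohort(adj, truth.signature.up)
    is_normal = ann.sample_class == "normal"
    thr = pf.calibrate_threshold(scores.raw[is_normal])
    called = pf.classify_samples(scores, thr.value)
    return adj, ann, truth, called


class TestGenesetCorrelations:
    def test_signature_itself_correlates_near_one(self, scored_cohort):
        adj, ann, truth, called = scored_cohort
        tumors = adj.subset_class("tumor")
        pi = pf.score_cohort(tumors, truth.signature.up)
        out = pf.correlate_with_genesets(
            pi, tumors, {"PI": truth.signature.up}
        )
        assert out.loc["PI", "pooled"] > 0.99

    def test_random_geneset_uncorrelated(self):
        # independence needs a realistically large gene universe: rank
        # scoring is compositional, so in tiny universes promoting the
        # signature mechanically demotes every other set
        cfg = pf.SimConfig(seed=53, n_genes=3000, n_tumors_per_tissue=150,
                           n_normals_per_tissue=100,
                           n_inflammatory_genes=300)
        normals, _ = pf.simulate_reference_normals(cfg)
        expr, ann, truth = pf.simulate_tumor_cohort(cfg)
        model = pf.fit_infiltration_slopes(normals)
        tumors = pf.adjust_expression(expr, model).matrix.subset_class("tumor")
        pi = pf.score_cohort(tumors, truth.signature.up)
        background = [g for g in tumors.genes if g.startswith("G")][:40]
        out = pf.correlate_with_genesets(pi, tumors, {"rand": background})
        assert abs(out.loc["rand", "pooled"]) < 0.2

    def test_coupled_program_recovered(self):
        cfg = pf.SimConfig(seed=43, n_genes=500, coactivated_genes=40,
                           n_tumors_per_tissue=200, n_normals_per_tissue=100,
                           pi_positive_fraction=0.4, noise_sd=0.1,
                           mean_genes_activated=30,
                           n_inflammatory_genes=100)
        normals, _ = pf.simulate_reference_normals(cfg)
        expr, ann, truth = pf.simulate_tumor_cohort(cfg)
        model = pf.fit_infiltration_slopes(normals)
        tumors = pf.adjust_expression(expr, model).matrix.subset_class("tumor")
        pi = pf.score_cohort(tumors, truth.signature.up)
        coupled = [g for g in tumors.genes if g.startswith("CO")]
        out = pf.correlate_with_genesets(pi, tumors, {"coupled": coupled})
        assert out.loc["coupled", "pooled"] > 0.5

    def test_fully_absent_geneset_yields_nan_with_warning(self, scored_cohort):
        adj, _, truth, called = scored_cohort
        with pytest.warns(UserWarning, match="absent"):
            out = pf.correlate_with_genesets(
                called, adj, {"ghost": ["NOPE1", "NOPE2"]}
            )
        assert np.isnan(out.loc["ghost", "pooled"])


class TestCytolyticActivity:
    def test_closed_form_on_three_sample_toy(self):
        vals = pd.DataFrame(
            {"s1": [3.0, 5.0], "s2": [2.0, 2.0], "s3": [0.0, 4.0]},
            index=["GZMA", "PRF1"],
        )
        out = pf.cytolytic_activity(ExpressionMatrix(vals))
        expected = [np.sqrt(2**3 * 2**5), np.sqrt(2**2 * 2**2),
                    np.sqrt(2**0 * 2**4)]
        assert out.tolist() == pytest.approx(expected)

    def test_equal_markers_give_their_common_level(self):
        vals = pd.DataFrame({"s": [4.0, 4.0]}, index=["GZMA", "PRF1"])
        out = pf.cytolytic_activity(ExpressionMatrix(vals), log_input=False)
        assert out["s"] == pytest.approx(4.0)

    def test_zero_expression_with_pseudocount(self):
        vals = pd.DataFrame({"s": [0.0, 9.0]}, index=["GZMA", "PRF1"])
        out = pf.cytolytic_activity(ExpressionMatrix(vals), log_input=False)
        assert out["s"] == 0.0
        out_pc = pf.cytolytic_activity(
            ExpressionMatrix(vals), log_input=False, pseudocount=1.0
        )
        assert out_pc["s"] == pytest.approx(np.sqrt(10.0))

    def test_missing_marker_rejected(self):
        vals = pd.DataFrame({"s": [1.0]}, index=["GZMA"])
        with pytest.raises(pf.ParainflamError):
            pf.cytolytic_activity(ExpressionMatrix(vals))


class TestP53Association:
    def test_identical_distributions_show_no_association(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=400),
                           index=[f"s{i}" for i in range(400)])
        status = pd.Series(np.where(np.arange(400) % 2, "mut", "WT"),
                           index=scores.index)
        res = pf.p53_association(scores, status)
        assert res["score_ranksum"].p > 0.05
        assert abs(res["score_ranksum"].effect) < 0.2

    def test_generated_logit_link_sign_recovered(self):
        cfg = pf.SimConfig(seed=47, n_genes=300, n_tumors_per_tissue=1000,
                           n_normals_per_tissue=20, n_inflammatory_genes=60)
        expr, ann, truth = pf.simulate_tumor_cohort(cfg)
        tum = ann.index[ann.sample_class == "tumor"]
        scores = pf.score_cohort(expr.subset_samples(list(tum)),
                                 truth.signature.up)
        calls = pd.Series(np.where(truth.pi_status[tum], "PI+", "PI-"),
                          index=tum)
        res = pf.p53_association(scores, truth.p53_status[tum], calls=calls)
        assert res["score_ranksum"].effect > 0
        assert res["score_ranksum"].p < 0.01
        assert res["pi_rate_chi2"].extras["prop_mut"] > \
            res["pi_rate_chi2"].extras["prop_WT"]
        assert res["pi_rate_chi2"].p < 0.01

    def test_single_status_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        status = pd.Series(["mut", "mut"], index=["a", "b"])
        with pytest.raises(pf.ParainflamError):
            pf.p53_association(scores, status)


class TestRankSumOracle:
    def test_matches_exact_enumeration_for_small_groups(self):
        """The U statistic's exact null distribution by enumeration."""
        x = np.array([1.2, 3.4, 0.2, 5.5])
        y = np.array([2.2, 4.1, 0.9])
        u_obs = stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
        pooled = np.concatenate([x, y])
        n_x = len(x)
        count_le = count_ge = total = 0

        def u_stat(xs, ys):
            return sum((xi > yi) + 0.5 * (xi == yi)
                       for xi in xs for yi in ys)

        observed = u_stat(x, y)
        mean_u = len(x) * len(y) / 2
        for idx in itertools.combinations(range(len(pooled)), n_x):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u = u_stat(xs, ys)
            total += 1
            if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
                count_ge += 1
        assert u_obs.pvalue == pytest.approx(count_ge / total)


class TestCoxSurvival:
    def test_constant_covariate_gives_zero_coefficient(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame({
            "time": rng.exponential(100, 50), "event": 1.0, "score": 2.0,
        })
        res = pf.cox_survival(rec)
        assert res.effect == 0.0

    def test_hazard_coefficient_recovered(self):
        # mean estimate over replicates within ±0.15 of the generating 0.8
        ests = []
        for seed in range(10):
            cfg = pf.SimConfig(seed=100 + seed, n_genes=200,
                               n_tumors_per_tissue=1000,
                               n_normals_per_tissue=20,
                               n_inflammatory_genes=50)
            _, ann, truth = pf.simulate_tumor_cohort(cfg)
            tum = ann.index[ann.sample_class == "tumor"]
            rec = pd.DataFrame({
                "time": ann.loc[tum, "time"],
                "event": ann.loc[tum, "event"],
                "score": truth.latent_intensity[tum],
            })
            ests.append(pf.cox_survival(rec).effect)
        assert np.mean(ests) == pytest.approx(0.8, abs=0.15)

    def test_null_hazard_is_calibrated(self):
        ps = []
        for seed in range(10):
            cfg = pf.SimConfig(seed=200 + seed, n_genes=200,
                               hazard_coef=0.0, n_tumors_per_tissue=300,
                               n_normals_per_tissue=20,
                               n_inflammatory_genes=50)
            _, ann, truth = pf.simulate_tumor_cohort(cfg)
            tum = ann.index[ann.sample_class == "tumor"]
            rec = pd.DataFrame({
                "time": ann.loc[tum, "time"],
                "event": ann.loc[tum, "event"],
                "score": truth.latent_intensity[tum],
            })
            ps.append(pf.cox_survival(rec).p)
        assert sum(p < 0.05 for p in ps) <= 3
        assert np.mean(ps) > 0.2

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": 0.0,
                            "score": [0.1, 0.2]})
        with pytest.raises(pf.ParainflamError):
            pf.cox_survival(rec)

    def test_cox_and_logrank_agree_in_sign(self, scored_cohort):
        adj, ann, truth, called = scored_cohort
        tum = ann.index[ann.sample_class == "tumor"]
        rec = pd.DataFrame({
            "time": ann.loc[tum, "time"],
            "event": ann.loc[tum, "event"],
            "score": called.raw[tum],
            "call": called.calls[tum],
        })
        cox = pf.cox_survival(rec)
        km = pf.km_logrank(rec)
        # positive hazard coefficient ⇔ PI+ median survival shorter
        assert cox.effect > 0
        ratio = km.effect  # PI− median / PI+ median
        assert ratio > 1


class TestKaplanMeier:
    def test_identical_groups_show_no_difference(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(50, 200)
        rec = pd.DataFrame({
            "time": np.concatenate([t, t]),
            "event": 1.0,
            "call": ["A"] * 200 + ["B"] * 200,
        })
        res = pf.km_logrank(rec)
        assert res.p > 0.9
        assert res.effect == pytest.approx(1.0)

    def test_product_limit_matches_hand_computation(self):
        # classic 6-record toy: deaths at 3, 5, 9; censoring at 4, 7, 11
        rec = pd.DataFrame({
            "time": [3, 4, 5, 7, 9, 11],
            "event": [1, 0, 1, 0, 1, 0],
            "call": "A",
        })
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(rec.time, rec.event)
        surv = km.survival_function_["KM_estimate"]
        # S(3)=5/6; S(5)=5/6·3/4; S(9)=5/6·3/4·1/2
        assert surv.loc[3.0] == pytest.approx(5 / 6)
        assert surv.loc[5.0] == pytest.approx(5 / 6 * 3 / 4)
        assert surv.loc[9.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert surv.loc[0.0] == 1.0
        assert (surv.diff().dropna() <= 1e-12).all()

    def test_km_plot_written(self, tmp_path):
        rng = np.random.default_rng(7)
        rec = pd.DataFrame({
            "time": rng.exponential(50, 100),
            "event": rng.integers(0, 2, 100).astype(float),
            "call": ["A"] * 50 + ["B"] * 50,
        })
        res = pf.km_logrank(rec)
        out = tmp_path / "km.png"
        from parainflam.association import plot_km_curves
        plot_km_curves(res, out)
        assert out.stat().st_size > 0

    def test_all_censored_group_has_undefined_median(self):
        rec = pd.DataFrame({
            "time": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
            "event": [0, 0, 0, 1, 1, 1],
            "call": ["A", "A", "A", "B", "B", "B"],
        })
        res = pf.km_logrank(rec)
        assert res.extras["medians"]["A"] is None
        assert np.isnan(res.effect)


class TestNsaidResponse:
    def _logfc(self, rng, shift):
        bg = pd.Series(rng.normal(0, 0.5, 5000),
                       index=[f"b{i}" for i in range(5000)])
        sig = pd.Series(rng.normal(shift, 0.5, 40),
                        index=[f"s{i}" for i in range(40)])
        return pd.concat([bg, sig]), list(sig.index)

    def test_null_signature_gives_uniformish_p(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(20):
            logfc, sig = self._logfc(rng, 0.0)
            ps.append(pf.nsaid_response_test(logfc, sig).p)
        assert sum(p < 0.05 for p in ps) <= 4
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_signature_strongly_detected(self):
        rng = np.random.default_rng(4)
        logfc, sig = self._logfc(rng, -1.0)
        res = pf.nsaid_response_test(logfc, sig)
        assert res.p < 1e-4
        assert res.effect < 0
        assert res.extras["fraction_signature_down"] > 0.8

    def test_all_tied_fold_changes_give_p_one(self):
        logfc = pd.Series(0.5, index=[f"g{i}" for i in range(100)])
        res = pf.nsaid_response_test(logfc, [f"g{i}" for i in range(10)])
        assert res.p == 1.0

    def test_insufficient_signature_coverage_rejected(self):
        logfc = pd.Series([0.1], index=["x"])
        with pytest.raises(pf.ParainflamError):
            pf.nsaid_response_test(logfc, ["a", "b", "x"])


class TestOrderInvariance:
    def test_statistics_invariant_to_sample_order(self, scored_cohort):
        adj, ann, truth, called = scored_cohort
        tum = list(ann.index[ann.sample_class == "tumor"])
        rec = pd.DataFrame({
            "time": ann.loc[tum, "time"],
            "event": ann.loc[tum, "event"],
            "score": called.raw[tum],
            "call": called.calls[tum],
        })
        rng = np.random.default_rng(5)
        shuffled = rec.iloc[rng.permutation(len(rec))]
        assert pf.cox_survival(rec).effect == pytest.approx(
            pf.cox_survival(shuffled).effect
        )
        assert pf.km_logrank(rec).p == pytest.approx(
            pf.km_logrank(shuffled).p
        )
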