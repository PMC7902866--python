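import numpy as np
import pandas as pd
import pytest

from mcpain import default_parcellation, toy_parcellation
from mcpain.errors import InvalidParameterError
from mcpain.evaluation import (
    compare_correlations,
    compare_error_sets,
    compute_pain_scores,
    evaluate_predictions,
    lobe_pair_counts,
    loocv,
    mae,
    mc_gmv_correlation,
    mrae,
    pearson_r,
)


def _pheno(laser, cold):
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(len(laser))],
            "laser_threshold_J": laser,
            "cold_threshold_s": cold,
        }
    )


class TestPainScores:
    def test_score_is_mean_of_normalized_thresholds(self):
        out = compute_pain_scores(_pheno([1.75, 2.0, 4.25], [5.0, 9.0, 13.0]))
        assert out["pain_sensitivity_score"].iloc[0] == pytest.approx(0.0)
        assert out["pain_sensitivity_score"].iloc[2] == pytest.approx(1.0)
        mid = (0.25 / 2.5 + 4.0 / 8.0) / 2
        assert out["pain_sensitivity_score"].iloc[1] == pytest.approx(mid)

    def test_scores_in_unit_interval(self, small_cohort):
        _, _, pheno, _ = small_cohort
        out = compute_pain_scores(pheno)
        s = out["pain_sensitivity_score"]
        assert s.between(0.0, 1.0).all()

    def test_constant_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_pain_scores(_pheno([2.0, 2.0], [5.0, 9.0]))


class TestMetrics:
    def test_enumerated_examples(self):
        assert mae([2, 3], [2.5, 2.5])[0] == pytest.approx(0.5)
        assert mrae([1.1, 1.8], [1.0, 2.0])[0] == pytest.approx(0.1)
        assert mae([1, 2], [1, 2])[0] == 0.0
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_match_one_line_oracles_to_1e12(self, rng):
        y = rng.normal(size=50) + 3
        yh = y + rng.normal(size=50)
        assert abs(mae(yh, y)[0] - np.mean(np.abs(yh - y))) < 1e-12
        assert abs(mrae(yh, y)[0] - np.mean(np.abs((yh - y) / y))) < 1e-12
        assert abs(pearson_r(yh, y) - np.corrcoef(yh, y)[0, 1]) < 1e-12

    def test_mrae_refuses_zero_truth(self):
        with pytest.raises(InvalidParameterError):
            mrae([1.0, 1.0], [0.0, 2.0])


class TestLOOCV:
    def test_exact_recovery_in_noise_free_linear_case(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -0.5, 2.0]) + 0.7
        preds = loocv(X, y, pls_options={"n_components": 3})
        assert np.max(np.abs(preds - y)) < 1e-6 * np.abs(y).max()

    def test_fold_count_and_row_order_invariance(self, rng):
        X = rng.normal(size=(15, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=15)
        preds = loocv(X, y)
        assert preds.shape == (15,)
        perm = rng.permutation(15)
        preds_perm = loocv(X[perm], y[perm])
        assert np.allclose(preds_perm, preds[perm], atol=1e-10)

    def test_returns_per_fold_alphas(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        _, alphas = loocv(X, y, return_alphas=True)
        assert alphas.shape == (12, 6)


class TestCompareErrorSets:
    def test_identical_error_vectors_give_p_one(self):
        errs = np.array([0.1, 0.5, 0.3, 0.7])
        res = compare_error_sets(errs, errs.copy())
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_statistic_equals_exact_enumeration_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        # brute-force U: count pairs (i, j) with a_i > b_j (+0.5 for ties)
        u = sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0) for ai in a for bj in b
        )
        res = compare_error_sets(a, b)
        assert res.statistic == pytest.approx(u)

    def test_shifted_distributions_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.5, 1, 200)
        assert compare_error_sets(a, b).p_value < 0.01

    def test_rejection_rate_calibrated_under_null(self):
        # identical generating distributions: reject at alpha=0.05 in <=9%
        rejections = 0
        for i in range(200):
            r = np.random.default_rng(10_000 + i)
            if compare_error_sets(r.normal(size=40), r.normal(size=40)).p_value < 0.05:
                rejections += 1
        assert rejections / 200 <= 0.09


class TestCompareCorrelations:
    def test_identical_predictions_give_p_one(self, rng):
        y = rng.normal(size=40)
        p = y + rng.normal(size=40)
        assert compare_correlations(p, p.copy(), y, seed=1).p_value == 1.0

    def test_zero_bootstrap_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(InvalidParameterError):
            compare_correlations(y, y, y, n_boot=0)

    def test_null_rejection_rate_within_band(self):
        # independent noise predictors: rejection rate in [0.02, 0.09]
        rejections = 0
        for i in range(200):
            r = np.random.default_rng(20_000 + i)
            y = r.normal(size=60)
            pa, pb = r.normal(size=60), r.normal(size=60)
            res = compare_correlations(pa, pb, y, n_boot=500, seed=i)
            if res.p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.09

    def test_clear_difference_detected(self, rng):
        y = rng.normal(size=100)
        good = y + 0.3 * rng.normal(size=100)
        bad = rng.normal(size=100)
        res = compare_correlations(good, bad, y, seed=3)
        assert res.p_value < 0.01
        assert res.statistic > 0


class TestLobePairCounts:
    def test_three_edges_in_one_lobe_pair(self):
        parc = default_parcellation()
        # prefrontal_L - prefrontal_R edges
        names = [
            "Frontal_Sup_L-Frontal_Mid_R",
            "Frontal_Mid_L-Frontal_Sup_R",
            "Rectus_L-Frontal_Med_Orb_R",
        ]
        summary = lobe_pair_counts(names, parc)
        assert summary.counts == {("prefrontal_L", "prefrontal_R"): 3}
        assert summary.total == 3

    def test_counts_conserve_total(self, small_cohort, parc8):
        _, _, _, truth = small_cohort
        summary = lobe_pair_counts(truth.planted_pair_names, parc8)
        assert sum(summary.counts.values()) == len(truth.planted_pair_names)

    def test_top_k_matches_planted_pairs(self):
        parc = default_parcellation()
        names = (
            ["Calcarine_L-Cuneus_L"] * 4
            + ["Hippocampus_L-Amygdala_L"] * 2
            + ["Insula_L-Thalamus_R"]
        )
        summary = lobe_pair_counts(names, parc, top_k=2)
        top = [pair for pair, _ in summary.top_k]
        assert top == [
            ("occipital_L", "occipital_L"),
            ("limbic_L", "limbic_L"),
        ]

    def test_set_algebra_between_threshold_types(self):
        parc = default_parcellation()
        a = lobe_pair_counts(["Calcarine_L-Cuneus_L", "Insula_L-Thalamus_R"], parc)
        b = lobe_pair_counts(["Calcarine_L-Lingual_L"], parc)
        assert a.common_pairs(b) == {("occipital_L", "occipital_L")}
        assert a.unique_pairs(b) == {("insula_L", "subcortical_R")}


class TestMCGMVCorrelation:
    def test_duplicated_column_gives_unit_correlation(self, rng):
        g = pd.DataFrame({"gA": rng.normal(size=30)}, index=range(30))
        m = pd.DataFrame({"mA": g["gA"], "mB": rng.normal(size=30)}, index=range(30))
        out = mc_gmv_correlation(m, g)
        row = out[(out.mc_feature == "mA") & (out.gmv_feature == "gA")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_null_significant_fraction_bounded(self):
        r = np.random.default_rng(77)
        m = pd.DataFrame(r.normal(size=(100, 40)))
        m.columns = [f"m{i}" for i in range(40)]
        g = pd.DataFrame(r.normal(size=(100, 10)))
        g.columns = [f"g{i}" for i in range(10)]
        out = mc_gmv_correlation(m, g, q=0.05)
        assert out.significant.mean() <= 0.07

    def test_participant_permutation_invariance(self, rng):
        idx = [f"p{i}" for i in range(25)]
        m = pd.DataFrame(rng.normal(size=(25, 5)), index=idx)
        g = pd.DataFrame(rng.normal(size=(25, 3)), index=idx)
        out1 = mc_gmv_correlation(m, g)
        perm = rng.permutation(25)
        out2 = mc_gmv_correlation(m.iloc[perm], g.iloc[perm])
        assert np.allclose(out1.r, out2.r)

    def test_constant_feature_flagged_not_fatal(self, rng):
        m = pd.DataFrame({"m0": np.ones(20), "m1": rng.normal(size=20)})
        g = pd.DataFrame({"g0": rng.normal(size=20)})
        out = mc_gmv_correlation(m, g)
        assert out[out.mc_feature == "m0"].undefined.all()
        assert not out[out.mc_feature == "m1"].undefined.any()


def test_evaluation_report_assembly(rng):
    y = rng.normal(size=20) + 5
    yh = y + 0.1 * rng.normal(size=20)
    rep = evaluate_predictions(yh, y, feature_set="mc", threshold_type="laser")
    assert rep.n == 20
    assert rep.mae == pytest.approx(np.mean(np.abs(yh - y)))
    frame = rep.to_frame()
    assert set(frame.columns) >= {"participant_id", "y_true", "y_pred", "abs_error"}
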