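import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import comb

from episcore.io import ValidationError
from episcore.mmlr import (
    EpiScoreRegressor,
    RidgeLogisticRegression,
    actual_vs_predicted_correlation,
    cross_validated_logistic,
    encode_traits,
    fit_mmlr,
    group_score_test,
    loocv_episcores,
    predict_traits,
    roc_auc,
)


class TestEncodeTraits:
    def test_documented_encoding_row(self, toy_metadata):
        T = encode_traits(toy_metadata, traits=("age", "sex", "cmv", "atg", "transplant"),
                          include_ancestry_pcs=False)
        row = T.loc["S0_x"]
        # age 40, F->0, CMV positive->1, ATG yes->1, post->1
        assert list(row) == [40.0, 0.0, 1.0, 1.0, 1.0]

    def test_constant_column_warns(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["sex"] = "F"
        with pytest.warns(UserWarning, match="constant"):
            encode_traits(meta, traits=("age", "sex"), include_ancestry_pcs=False)

    def test_trait_selection_controls_columns(self, toy_metadata):
        T = encode_traits(toy_metadata, traits=("age",), include_ancestry_pcs=False)
        assert list(T.columns) == ["age"]
        T2 = encode_traits(toy_metadata, traits=("age",), include_ancestry_pcs=True)
        assert list(T2.columns) == ["age", "ancestry_pc1"]


class TestFitPredict:
    def test_identity_design_returns_matrix(self, rng):
        M = rng.random((5, 8))  # samples x sites
        model = EpiScoreRegressor().fit(M, np.eye(5))
        np.testing.assert_allclose(model.coef_, M, atol=1e-12)

    def test_exact_recovery_matches_normal_equation_oracle(self, rng):
        T = rng.standard_normal((4, 2))
        C_true = rng.standard_normal((2, 6))
        M = T @ C_true
        C = EpiScoreRegressor().fit(M, T).coef_
        np.testing.assert_allclose(C, C_true, atol=1e-10)
        oracle = np.linalg.solve(T.T @ T, T.T @ M)
        np.testing.assert_allclose(C, oracle, atol=1e-10)

    def test_rank_deficient_design_gives_minimum_norm_solution(self, rng):
        T = rng.standard_normal((6, 2))
        T = np.column_stack([T, T[:, 0]])  # duplicated trait column
        M = rng.random((6, 10))
        C = EpiScoreRegressor().fit(M, T).coef_
        oracle = np.linalg.pinv(T) @ M
        np.testing.assert_allclose(C, oracle, atol=1e-10)
        assert np.linalg.norm(C) == pytest.approx(np.linalg.norm(oracle))

    def test_fit_matches_per_site_svd_least_squares_over_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T = rng.standard_normal((10, 4))
            M = rng.standard_normal((10, 20))
            C = EpiScoreRegressor().fit(M, T).coef_
            oracle = np.stack(
                [np.linalg.lstsq(T, M[:, j], rcond=None)[0] for j in range(20)], axis=1
            )
            np.testing.assert_allclose(C, oracle, atol=1e-9)

    def test_noiseless_fit_predict_recovers_traits(self, rng):
        T = rng.standard_normal((12, 3))
        C_true = rng.standard_normal((3, 30))
        M = T @ C_true
        model = EpiScoreRegressor().fit(M, T)
        np.testing.assert_allclose(model.predict(M).to_numpy(), T, atol=1e-8)

    def test_prediction_is_stateless_across_batches(self, rng):
        T = rng.standard_normal((10, 3))
        M = rng.random((10, 25))
        model = EpiScoreRegressor().fit(M, T)
        X_new = rng.random((4, 25))
        alone = model.predict(X_new[:1]).to_numpy()
        batch = model.predict(X_new).to_numpy()
        np.testing.assert_allclose(alone[0], batch[0], atol=1e-12)

    def test_small_worked_case_against_svd_pseudoinverse(self, rng):
        C = rng.standard_normal((2, 4))
        M_new = pd.DataFrame(rng.random((4, 3)),
                             index=[f"chr1:{i + 1}" for i in range(4)],
                             columns=list("abc"))
        Cdf = pd.DataFrame(C, index=["t1", "t2"], columns=M_new.index)
        got = predict_traits(M_new, Cdf).to_numpy()
        U, S, Vt = np.linalg.svd(C, full_matrices=False)
        C_pinv = Vt.T @ np.diag(1 / S) @ U.T
        np.testing.assert_allclose(got, M_new.T.to_numpy() @ C_pinv, atol=1e-10)

    def test_dimension_and_alignment_errors(self, rng):
        with pytest.raises(ValidationError, match="dimension mismatch"):
            EpiScoreRegressor().fit(rng.random((5, 4)), rng.random((6, 2)))
        model = EpiScoreRegressor().fit(rng.random((5, 4)), rng.random((5, 2)))
        with pytest.raises(ValidationError, match="site misalignment"):
            model.predict(rng.random((3, 7)))

    def test_fit_mmlr_wrapper_orientation(self, rng):
        M = pd.DataFrame(rng.random((6, 4)),
                         index=[f"chr1:{i + 1}" for i in range(6)],
                         columns=list("wxyz"))
        T = pd.DataFrame(rng.standard_normal((4, 2)), index=list("wxyz"),
                         columns=["age", "atg"])
        C = fit_mmlr(T, M)
        assert C.shape == (2, 6)
        assert list(C.index) == ["age", "atg"]
        np.testing.assert_allclose(C.to_numpy(),
                                   np.linalg.pinv(T.to_numpy()) @ M.to_numpy().T)


class TestLoocv:
    def test_fold_isolation(self, rng):
        """Perturbing a sample's own trait never changes its own epi score."""
        T = pd.DataFrame(rng.standard_normal((12, 2)), columns=["a", "b"])
        M = pd.DataFrame(rng.random((30, 12)), columns=T.index)
        base = loocv_episcores(T, M).scores
        T2 = T.copy()
        T2.iloc[0, 0] += 100.0
        pert = loocv_episcores(T2, M).scores
        np.testing.assert_allclose(base.iloc[0], pert.iloc[0], atol=1e-10)
        # but other samples' scores do change (sample 0 is in their folds)
        assert not np.allclose(base.iloc[1], pert.iloc[1])

    def test_heldout_score_equals_fit_without_sample(self, rng):
        T = pd.DataFrame(rng.standard_normal((10, 2)))
        M = pd.DataFrame(rng.random((20, 10)), columns=T.index)
        panel = loocv_episcores(T, M)
        model = EpiScoreRegressor().fit(M.T.drop(index=0), T.drop(index=0))
        manual = model.predict(M.T.loc[[0]]).to_numpy()[0]
        np.testing.assert_allclose(panel.scores.iloc[0].to_numpy(), manual, atol=1e-10)

    def test_group_loocv_holds_out_whole_subject(self, rng):
        n = 12
        groups = pd.Series(np.repeat(np.arange(n // 2), 2))
        T = pd.DataFrame(rng.standard_normal((n, 2)))
        M = pd.DataFrame(rng.random((25, n)), columns=T.index)
        panel = loocv_episcores(T, M, groups=groups)
        model = EpiScoreRegressor().fit(M.T.drop(index=[0, 1]), T.drop(index=[0, 1]))
        manual = model.predict(M.T.loc[[0]]).to_numpy()[0]
        np.testing.assert_allclose(panel.scores.iloc[0].to_numpy(), manual, atol=1e-10)

    def test_constant_binary_fold_warns_but_predicts(self, rng):
        T = pd.DataFrame({"b": [1.0] + [0.0] * 9, "x": rng.standard_normal(10)})
        M = pd.DataFrame(rng.random((15, 10)), columns=T.index)
        with pytest.warns(UserWarning, match="constant in a training fold"):
            panel = loocv_episcores(T, M)
        assert np.isfinite(panel.scores.to_numpy()).all()


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_equal_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_ties_match_exhaustive_pair_enumeration(self):
        scores = np.array([0.1, 0.4, 0.4, 0.7, 0.2, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        total = 0.0
        for i in np.where(labels == 1)[0]:
            for j in np.where(labels == 0)[0]:
                total += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
        expected = total / (labels.sum() * (1 - labels).sum())
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestGroupTest:
    def test_fully_separated_groups_match_exact_enumeration(self, rng):
        a = np.arange(10) + 100.0
        b = np.arange(10) * 1.0
        p = group_score_test(np.concatenate([a, b]), [1] * 10 + [0] * 10)
        assert p == pytest.approx(2.0 / comb(20, 10), rel=1e-10)

    def test_identical_distributions_p_not_small(self, rng):
        ps = [group_score_test(rng.standard_normal(40), [0, 1] * 20)
              for _ in range(20)]
        assert 0.25 < np.mean(ps) < 0.75

    def test_tie_heavy_input_yields_finite_p(self):
        p = group_score_test([1, 1, 1, 2, 2, 1, 1, 2], [0, 0, 0, 0, 1, 1, 1, 1])
        assert np.isfinite(p) and 0 <= p <= 1


class TestSpearmanPanel:
    def test_perfect_prediction_rho_one(self, rng):
        from episcore.mmlr import EpiScorePanel
        T = pd.DataFrame({"age": rng.random(10)})
        panel = EpiScorePanel(scores=T.copy())
        rho, _ = actual_vs_predicted_correlation(T, panel)
        assert rho.loc["age", "age"] == pytest.approx(1.0)

    def test_hand_case_matches_rank_then_pearson(self):
        from episcore.mmlr import EpiScorePanel
        x = pd.DataFrame({"t": [3.0, 1.0, 4.0, 1.5, 5.0]})
        y = pd.DataFrame({"t": [2.0, 0.5, 3.0, 1.0, 10.0]})
        rho, _ = actual_vs_predicted_correlation(x, EpiScorePanel(scores=y))
        rx = pd.Series(x["t"]).rank()
        ry = pd.Series(y["t"]).rank()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["t", "t"] == pytest.approx(expected)

    def test_constant_vector_warns_and_stays_missing(self, rng):
        from episcore.mmlr import EpiScorePanel
        T = pd.DataFrame({"t": np.ones(5)})
        panel = EpiScorePanel(scores=pd.DataFrame({"t": rng.random(5)}))
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = actual_vs_predicted_correlation(T, panel)
        assert np.isnan(rho.loc["t", "t"])


class TestRidgeLogistic:
    def test_huge_penalty_shrinks_coefficients_to_zero(self, rng):
        X = rng.standard_normal((30, 3))
        y = (rng.random(30) > 0.5).astype(float)
        clf = RidgeLogisticRegression(penalty=1e8).fit(X, y)
        assert np.abs(clf.coef_).max() < 1e-4

    def test_separable_one_site_toy_out_of_fold_auc_one(self):
        M = pd.DataFrame([np.r_[np.zeros(10), np.ones(10)] * 0.8 + 0.1],
                         index=["chr1:1"], columns=[f"s{i}" for i in range(20)])
        y = np.r_[np.zeros(10), np.ones(10)]
        _, auc = cross_validated_logistic(M, y, penalty=1.0, folds=5)
        assert auc == 1.0

    def test_coefficients_match_direct_minimizer_of_penalized_logloss(self, rng):
        X = rng.standard_normal((20, 5))
        beta = np.array([1.0, -1.0, 0.5, 0.0, 0.2])
        y = (rng.random(20) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        clf = RidgeLogisticRegression(penalty=1.0, fit_intercept=True).fit(X, y)

        def loss(w):
            eta = w[0] + X @ w[1:]
            return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * np.sum(w[1:] ** 2)

        res = minimize(loss, np.zeros(6), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(np.r_[clf.intercept_, clf.coef_], res.x, atol=1e-4)

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        X = rng.standard_normal((20, 2)) * 100
        y = (X[:, 0] > 0).astype(float)  # separable: unpenalized IRLS diverges
        with pytest.raises(ValidationError, match="did not converge"):
            RidgeLogisticRegression(penalty=0.0, max_iter=5).fit(X, y)
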