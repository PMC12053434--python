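import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcore.association import (
    bh_adjust,
    build_design,
    fit_sitewise_models,
    methylation_expression_correlation,
    select_trait_associated_sites,
)
from episcore.io import ValidationError
from episcore.simulate import SimulationConfig, make_site_gene_mapping, simulate_expression


def _sitewise(rng, n=30, p=3, n_sites=5):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"c{i}" for i in range(p)])
    M = pd.DataFrame(rng.random((n_sites, n)),
                     index=[f"chr1:{i + 1}" for i in range(n_sites)],
                     columns=[f"s{i}" for i in range(n)])
    X.index = M.columns
    return M, build_design(X)


class TestSitewiseOls:
    def test_exact_linear_site_recovers_coefficient(self, rng):
        n = 24
        atg = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        other = np.tile([1, -1], n // 2) * 0.3  # orthogonal to atg
        y = 2.0 * atg
        M = pd.DataFrame([np.clip(y / 4 + 0.1, 0, 1)], index=["chr1:1"],
                         columns=[f"s{i}" for i in range(n)])
        design = pd.DataFrame({"intercept": 1.0, "atg": atg, "other": other},
                              index=M.columns)
        res = fit_sitewise_models(M, design)
        assert res.beta.loc["chr1:1", "atg"] == pytest.approx(0.5, abs=1e-10)
        assert res.pvalue.loc["chr1:1", "atg"] < 1e-20

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        M, design = _sitewise(rng, n=30, p=3, n_sites=6)
        res = fit_sitewise_models(M, design)
        for site in M.index:
            fit = sm.OLS(M.loc[site].to_numpy(), design.to_numpy()).fit()
            np.testing.assert_allclose(res.beta.loc[site].to_numpy(), fit.params,
                                       atol=1e-10)
            np.testing.assert_allclose(res.se.loc[site].to_numpy(), fit.bse,
                                       atol=1e-10)
            np.testing.assert_allclose(res.pvalue.loc[site].to_numpy(), fit.pvalues,
                                       atol=1e-10)

    def test_six_sample_hand_case_matches_normal_equations(self):
        y = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.6])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        M = pd.DataFrame([y], index=["chr1:1"], columns=list("abcdef"))
        design = pd.DataFrame({"intercept": 1.0, "x": x}, index=M.columns)
        res = fit_sitewise_models(M, design)
        A = design.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(res.beta.loc["chr1:1"].to_numpy(), beta, atol=1e-10)

    def test_null_pvalues_uniform(self, rng):
        n, n_sites = 50, 1000
        X = pd.DataFrame({"intercept": 1.0,
                          "atg": (rng.random(n) > 0.5).astype(float),
                          "age": rng.uniform(20, 70, n)})
        M = pd.DataFrame(np.clip(0.5 + rng.normal(0, 0.05, (n_sites, n)), 0, 1),
                         index=[f"chr1:{i + 1}" for i in range(n_sites)],
                         columns=X.index)
        res = fit_sitewise_models(M, X)
        ks = stats.kstest(res.pvalue["atg"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_design_rejected_naming_columns(self, rng):
        X = pd.DataFrame({"a": rng.random(10)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValidationError, match="collinear.*'b'"):
            build_design(X, add_intercept=False)

    def test_constant_column_pruned_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.random(10), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            design = build_design(X)
        assert list(design.columns) == ["intercept", "a"]

    def test_sample_misalignment_rejected(self, rng):
        M, design = _sitewise(rng)
        with pytest.raises(ValidationError, match="align"):
            fit_sitewise_models(M, design.iloc[::-1])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # p(i) * n / i then cumulative min from the largest rank
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])
        got = bh_adjust([0.01, 0.04, 0.03, 0.002])
        np.testing.assert_allclose(got, [0.02, 0.04, 0.04, 0.008])

    def test_degenerate_lists(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_permutation_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw_and_in_unit_interval(self, rng):
        p = rng.random(100) ** 2
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestSiteSelection:
    def test_direction_and_alpha_filters(self, rng):
        M, design = _sitewise(rng, n=40, n_sites=20)
        res = fit_sitewise_models(M, design)
        assert select_trait_associated_sites(res, "c0", alpha=0.0) == []
        pos = select_trait_associated_sites(res, "c0", alpha=1.0, direction="positive")
        neg = select_trait_associated_sites(res, "c0", alpha=1.0, direction="negative")
        both = select_trait_associated_sites(res, "c0", alpha=1.0, direction="both")
        assert sorted(pos + neg) == sorted(both)
        assert all(res.beta.loc[s, "c0"] > 0 for s in pos)
        with pytest.raises(ValidationError, match="unknown trait"):
            select_trait_associated_sites(res, "nope")

    def test_recall_nondecreasing_in_effect_size(self, small_panel):
        from episcore.simulate import simulate_cohort
        from episcore.mmlr import encode_traits
        panel, _ = small_panel
        recalls = []
        for eff in (0.02, 0.08, 0.15):
            cfg = SimulationConfig(seed=5, n_subjects=60, paired=False,
                                   n_sites=2000, noise_sd=0.05,
                                   trait_effects={"atg": (50, eff)})
            M, meta, truth = simulate_cohort(cfg, panel)
            T = encode_traits(meta, include_ancestry_pcs=False)
            res = fit_sitewise_models(M, build_design(T))
            sel = set(select_trait_associated_sites(res, "atg", 0.05, "positive"))
            true = set(truth.effect_sites["atg"].index)
            recalls.append(len(sel & true) / len(true))
        assert recalls == sorted(recalls)
        assert recalls[-1] > 0.9


class TestExpressionFilter:
    def test_constructed_anticorrelation_passes(self, small_cohort, small_config):
        M, _, truth = small_cohort
        cfg = SimulationConfig(seed=small_config.seed, n_sites=2000,
                               expr_slope=4.0, expr_noise_sd=0.2)
        mapping = make_site_gene_mapping(truth, "atg", n_sites=15)
        expr = simulate_expression(M, mapping, cfg, n_noise_genes=0)
        table = methylation_expression_correlation(M, expr, mapping)
        assert table["passes"].mean() > 0.9
        assert (table.loc[table["passes"], "r"] < -0.3).all()
        assert (table.loc[table["passes"], "direction"] == "down-regulation").all()
        # oracle: direct Pearson on one pair
        site, gene = next(iter(mapping.items()))
        r, p = stats.pearsonr(M.loc[site], expr.loc[gene])
        row = table.set_index("site").loc[site]
        assert row["r"] == pytest.approx(r) and row["p"] == pytest.approx(p)

    def test_perfect_linear_pair_r_is_minus_one(self):
        M = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["chr1:1"],
                         columns=list("abcd"))
        expr = pd.DataFrame([[4.0, 3.0, 2.0, 1.0]], index=["g"], columns=list("abcd"))
        table = methylation_expression_correlation(M, expr, {"chr1:1": "g"})
        assert table.loc[0, "r"] == pytest.approx(-1.0)

    def test_fewer_than_three_shared_samples_rejected(self):
        M = pd.DataFrame([[0.1, 0.2]], index=["chr1:1"], columns=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="3 shared"):
            methylation_expression_correlation(M, expr, {"chr1:1": "g"})
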