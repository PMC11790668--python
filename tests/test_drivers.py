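import itertools
import math

import numpy as np
import pandas as pd
import pytest

from forestdyn.drivers import (
    best_subset_aic,
    build_model_frame,
    dimension_importance,
    gaussian_aic,
    hierarchical_partition,
    predictor_dimension,
    run_driver_analysis,
    standardize,
    vif_filter,
    wilcoxon_compare,
)
from forestdyn.errors import InvalidConfigurationError, ValidationError


def random_frame(n, p, seed, collinear=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    if collinear:
        x[:, -1] = x[:, 0] + x[:, 1] + rng.normal(0, 0.01, n)
    return pd.DataFrame(x, columns=[f"x{i}" for i in range(p)])


class TestWilcoxon:
    def test_identical_samples_no_shift(self):
        agb = pd.DataFrame({1: np.arange(10.0), 2: np.arange(10.0)})
        out = wilcoxon_compare(agb)
        assert out["p_value"].iloc[0] >= 0.99

    def test_fully_separated_small_samples_exact(self):
        agb = pd.DataFrame({1: [1.0, 2.0, 3.0], 2: [10.0, 11.0, 12.0]})
        out = wilcoxon_compare(agb)
        # U = 0; the smallest attainable two-sided p over the 20 rankings
        assert out["p_value"].iloc[0] == pytest.approx(0.1)

    def test_rank_invariance_to_shift(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({1: rng.normal(size=12), 2: rng.normal(0.5, 1, 12)})
        b = a + 1000.0
        assert wilcoxon_compare(a)["p_value"].iloc[0] == pytest.approx(
            wilcoxon_compare(b)["p_value"].iloc[0])

    def test_exact_enumeration_oracle_small_n(self):
        # direct enumeration of all C(10,5) rank assignments
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(size=5)
        out = wilcoxon_compare(pd.DataFrame({1: x, 2: y}))
        combined = np.concatenate([x, y])
        ranks = pd.Series(combined).rank().to_numpy()
        u_obs = ranks[:5].sum() - 5 * 6 / 2
        us = []
        for comb in itertools.combinations(range(10), 5):
            us.append(ranks[list(comb)].sum() - 15)
        us = np.asarray(us)
        p_exact = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert out["p_value"].iloc[0] == pytest.approx(p_exact, abs=1e-9)

    def test_strata_and_paired_variants(self, small_results, small_study):
        agb = small_results["agb"]
        strata = small_study.landscape.frame["habitat"]
        out = wilcoxon_compare(agb, strata=strata)
        assert set(out["stratum"]) == {"whole", "H1", "H2", "H3"}
        paired = wilcoxon_compare(agb, strata=strata, paired=True)
        assert len(paired) == len(out)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = standardize(random_frame(50, 3, 0))
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_dropped(self):
        df = random_frame(20, 2, 1).assign(const_col=3.0)
        z = standardize(df)
        assert "const_col" not in z.columns

    def test_idempotent(self):
        z = standardize(random_frame(30, 3, 2))
        pd.testing.assert_frame_equal(standardize(z), z)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            standardize(random_frame(1, 2, 3))


class TestVif:
    def test_orthogonal_predictors_untouched(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(40, 4)))
        x = pd.DataFrame(q, columns=list("abcd"))
        kept, dropped = vif_filter(x, 5.0)
        assert dropped == [] and list(kept.columns) == list("abcd")

    def test_duplicated_column_removed(self):
        x = random_frame(30, 3, 5)
        x["x0_copy"] = x["x0"]
        kept, dropped = vif_filter(x, 5.0)
        assert len(dropped) == 1
        assert dropped[0][0] in ("x0", "x0_copy")
        assert len(kept.columns) == 3

    def test_near_collinear_trio_filtered_with_oracle_recheck(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        x = random_frame(60, 3, 6, collinear=True)
        kept, dropped = vif_filter(x, 5.0)
        assert len(dropped) >= 1
        arr = sm.add_constant(kept).to_numpy()
        for j in range(1, arr.shape[1]):
            assert variance_inflation_factor(arr, j) <= 5.0 + 1e-6


class TestBestSubset:
    def test_single_predictor_full_importance(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame({"x0": rng.normal(size=50)})
        y = pd.Series(0.8 * x["x0"] + rng.normal(0, 0.3, 50))
        model = best_subset_aic(x, y)
        assert model.predictors == ["x0"]
        part = hierarchical_partition(x, y, model.predictors)
        assert part["relative_importance"].iloc[0] == pytest.approx(100.0)

    def test_exact_signal_noise_predictor_rejected(self):
        rng = np.random.default_rng(8)
        x = random_frame(100, 2, 8)
        y = pd.Series(x["x0"].to_numpy())
        model = best_subset_aic(x, y)
        assert model.predictors == ["x0"]

    def test_enumeration_oracle_five_predictors(self):
        import statsmodels.api as sm

        x = random_frame(60, 5, 9)
        rng = np.random.default_rng(9)
        y = pd.Series(x["x1"] * 0.5 - x["x3"] * 0.7 + rng.normal(0, 1, 60))
        model = best_subset_aic(x, y)
        # statsmodels AIC as an independent criterion: same ranking
        best_oracle, best_aic = None, np.inf
        for k in range(1, 6):
            for comb in itertools.combinations(x.columns, k):
                fit = sm.OLS(y, sm.add_constant(x[list(comb)])).fit()
                if fit.aic < best_aic - 1e-10:
                    best_aic, best_oracle = fit.aic, list(comb)
        assert model.predictors == best_oracle

    def test_stepwise_fallback_runs_and_beats_full_model(self):
        rng = np.random.default_rng(10)
        x = random_frame(80, 17, 10)
        y = pd.Series(x["x2"] - 0.5 * x["x9"] + rng.normal(0, 1, 80))
        model = best_subset_aic(x, y, max_exhaustive=15)
        assert model.method == "stepwise"
        assert {"x2", "x9"} <= set(model.predictors)
        n = len(y)
        xmat = np.column_stack([np.ones(n), x.to_numpy()])
        beta, *_ = np.linalg.lstsq(xmat, y.to_numpy(), rcond=None)
        rss = float(((y.to_numpy() - xmat @ beta) ** 2).sum())
        assert model.aic <= gaussian_aic(rss, n, 17) + 1e-9


class TestHierarchicalPartition:
    def test_orthogonal_equal_signal_splits_evenly(self):
        # centered, mutually orthogonal ±1 contrasts with equal marginal R²
        a = np.tile([1.0, 1.0, -1.0, -1.0], 15)
        b = np.tile([1.0, -1.0, 1.0, -1.0], 15)
        x = pd.DataFrame({"a": a, "b": b})
        y = pd.Series(a + b)
        part = hierarchical_partition(x, y)
        assert part["relative_importance"].to_numpy() == pytest.approx([50.0, 50.0])

    def test_independent_contributions_sum_to_full_r2(self):
        rng = np.random.default_rng(12)
        x = random_frame(50, 5, 12)
        y = pd.Series(x.to_numpy() @ rng.normal(size=5) + rng.normal(0, 1, 50))
        part = hierarchical_partition(x, y)
        import statsmodels.api as sm

        full_r2 = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert part["independent"].sum() == pytest.approx(full_r2, abs=1e-10)

    def test_matches_all_orderings_average(self):
        rng = np.random.default_rng(13)
        x = random_frame(40, 4, 13)
        y = pd.Series(x.to_numpy() @ rng.normal(size=4) + rng.normal(0, 1, 40))
        part = hierarchical_partition(x, y)

        def r2(subset):
            if not subset:
                return 0.0
            xm = np.column_stack([np.ones(len(y)), x[list(subset)].to_numpy()])
            b, *_ = np.linalg.lstsq(xm, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - xm @ b
            return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

        orders = list(itertools.permutations(x.columns))
        avg = {c: 0.0 for c in x.columns}
        for order in orders:
            seen = []
            for c in order:
                avg[c] += r2(seen + [c]) - r2(seen)
                seen.append(c)
        for c in x.columns:
            assert part.at[c, "independent"] == pytest.approx(avg[c] / len(orders), abs=1e-10)

    def test_invariant_to_predictor_order(self):
        rng = np.random.default_rng(14)
        x = random_frame(40, 3, 14)
        y = pd.Series(x["x0"] + rng.normal(0, 1, 40))
        a = hierarchical_partition(x, y)
        b = hierarchical_partition(x[["x2", "x0", "x1"]], y)
        for c in x.columns:
            assert a.at[c, "independent"] == pytest.approx(b.at[c, "independent"], abs=1e-12)

    def test_combinatorial_bound(self):
        x = random_frame(40, 13, 15)
        with pytest.raises(InvalidConfigurationError):
            hierarchical_partition(x, pd.Series(np.zeros(40)))


class TestDimensions:
    def test_structural_grouping_of_change_values(self):
        for name in ("SD", "cSD", "CV_DBH", "cCV_DBH"):
            assert predictor_dimension(name) == "structural"
        assert predictor_dimension("convexity") == "topographic"
        assert predictor_dimension("cMPD") == "phylogenetic"
        assert predictor_dimension("ctraitMNTD") == "functional"

    def test_single_group_is_everything(self):
        part = pd.DataFrame({"relative_importance": [60.0, 40.0]}, index=["H", "cJ"])
        out = dimension_importance(part)
        assert out.to_dict() == {"taxonomic": pytest.approx(100.0)}

    def test_additivity_and_sum_to_100(self):
        part = pd.DataFrame({"relative_importance": [30.0, 45.0, 25.0]},
                            index=["SD", "cMPD", "elevation"])
        out = dimension_importance(part)
        assert out.sum() == pytest.approx(100.0)
        assert out["structural"] == pytest.approx(30.0)

    def test_unmapped_predictor_keyed_error(self):
        part = pd.DataFrame({"relative_importance": [100.0]}, index=["mystery"])
        with pytest.raises(KeyError):
            dimension_importance(part)


class TestDriverAnalysis:
    def test_default_study_yields_eight_cells(self, small_results):
        results = small_results["drivers"]
        assert len(results) == 8
        cells = {(r.interval, r.stratum) for r in results}
        assert cells == {(i, s) for i in ("1-2", "2-3")
                         for s in ("whole", "H1", "H2", "H3")}
        for r in results:
            assert abs(r.partition["relative_importance"].sum() - 100.0) < 1e-6
            assert abs(r.dimensions.sum() - 100.0) < 1e-6

    def test_small_stratum_skipped(self, small_results):
        cov = small_results["covariates"]
        out = run_driver_analysis(cov, strata=("H3",), min_n=50)
        assert out == []

    def test_model_frame_is_stratified_and_complete(self, small_results):
        cov = small_results["covariates"]
        frame = build_model_frame(cov, "1-2", "H1")
        assert frame.notna().all().all()
        assert len(frame) <= (cov["habitat"] == "H1").sum()

    def test_embedded_effect_recovered_single_replicate(self):
        from forestdyn.pipeline import PipelineConfig, compute_results
        from forestdyn.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(seed=21, n_species=40, initial_stems_mean=60, n_censuses=2,
                               embedded_effects=(("cMPD", 0.5),), noise_sd=1.0,
                               null_iterations=99)
        study = simulate_study(cfg)
        pc = PipelineConfig(null_iterations=99, seed=21, strata=("whole",))
        res = compute_results(study.censuses, study.species_pool,
                              study.landscape.corner_elevations,
                              study.landscape.frame["habitat"], pc)
        (r,) = res["drivers"]
        assert "cMPD" in r.model.predictors
        assert r.model.coefficients.at["cMPD", "coef"] > 0
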