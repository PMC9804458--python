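"""Monte Carlo sampling, credible intervals, phase-space bands and
scenario classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mesothresh as mt
from mesothresh.uncertainty import evaluate_draws


@pytest.fixture(scope="module")
def small_plan():
    return mt.SamplingPlan(n_draws=5000, seed=11)


@pytest.fixture(scope="module")
def band_table(pset_split, small_plan):
    return mt.phase_space_bands(pset_split.specs, small_plan, np.arange(0, 31.0))


class TestSampling:
    def test_same_seed_bit_identical(self, pset):
        plan = mt.SamplingPlan(n_draws=200, seed=42)
        a = mt.sample_parameters(pset.specs, plan)
        b = mt.sample_parameters(pset.specs, plan)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, pset):
        a = mt.sample_parameters(pset.specs, mt.SamplingPlan(n_draws=200, seed=1))
        b = mt.sample_parameters(pset.specs, mt.SamplingPlan(n_draws=200, seed=2))
        assert not a.equals(b)

    def test_temporal_parameters_held_fixed(self, pset, small_plan):
        draws = mt.sample_parameters(pset.specs, small_plan)
        for name in ("T_I", "T_H", "T_B", "T_mat", "alpha_M", "alpha_R"):
            assert draws[name].nunique() == 1

    def test_zero_cv_degenerates_to_means(self, pset):
        plan = mt.SamplingPlan(n_draws=50, seed=5, cv_default=0.0)
        draws = mt.sample_parameters(pset.specs, plan)
        means = pset.values()
        for name, mean in means.items():
            assert (draws[name] == mean).all()

    def test_ranged_parameter_truncation_and_moments(self, pset):
        # mu_A: mean 0.125, sd 0.025, truncated to the published 0.10-0.15
        plan = mt.SamplingPlan(n_draws=100_000, seed=9)
        draws = mt.sample_parameters(pset.specs, plan)["mu_A"]
        assert draws.between(0.10, 0.15).all()
        sd = 0.20 * 0.125
        a, b = (0.10 - 0.125) / sd, (0.15 - 0.125) / sd
        ref = stats.truncnorm(a, b, loc=0.125, scale=sd)
        se = ref.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - ref.mean()) < 3 * se

    def test_natural_domain_truncation_for_proportions(self, pset):
        plan = mt.SamplingPlan(n_draws=50_000, seed=9)
        draws = mt.sample_parameters(pset.specs, plan)
        assert draws["nu"].between(0, 1).all()
        assert (draws["preypref_E_R"] >= 0).all()

    def test_assumed_range_policy_tightens_rangeless_parameters(self, pset):
        plan = mt.SamplingPlan(n_draws=20_000, seed=9, truncation="assumed_range")
        draws = mt.sample_parameters(pset.specs, plan)
        assert draws["mu_J"].between(0.8 * 0.2, 1.2 * 0.2).all()

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            mt.SamplingPlan(n_draws=0)
        with pytest.raises(ValueError):
            mt.SamplingPlan(truncation="bogus")


class TestSummaries:
    def test_zero_cv_collapses_to_deterministic(self, pset_split, rates_split):
        plan = mt.SamplingPlan(n_draws=100, seed=3, cv_default=0.0)
        report = mt.monte_carlo_summary(pset_split.specs, plan)
        det = mt.summarize_thresholds(pset_split.demography, rates_split)
        expect = {
            "critical_rats": det.critical_rats,
            "cat_equivalence": det.cat_equivalence,
            "critical_cats": det.critical_cats,
        }
        for name, summary in report.outputs.items():
            assert summary.median == pytest.approx(expect[name], rel=1e-12)
            assert summary.ci95[0] == pytest.approx(summary.ci95[1], rel=1e-12)

    def test_quantile_nesting(self, pset, small_plan):
        report = mt.monte_carlo_summary(pset.specs, small_plan)
        for s in report.outputs.values():
            assert s.ci95[0] <= s.ci68[0] <= s.median <= s.ci68[1] <= s.ci95[1]

    def test_reproducibility(self, pset, small_plan):
        a = mt.monte_carlo_summary(pset.specs, small_plan)
        b = mt.monte_carlo_summary(pset.specs, small_plan)
        assert a == b

    def test_nonviable_draws_counted_not_summarised(self, pset, small_plan):
        draws = mt.sample_parameters(pset.specs, small_plan)
        out, valid, viable = evaluate_draws(draws)
        report = mt.monte_carlo_summary(pset.specs, small_plan)
        assert report.n_invalid == int((~viable).sum())
        assert report.outputs["critical_rats"].ci95[0] > 0.0

    def test_median_standard_error_shrinks_with_draws(self, pset):
        def medians(n, seeds):
            out = []
            for s in seeds:
                rep = mt.monte_carlo_summary(
                    pset.specs, mt.SamplingPlan(n_draws=n, seed=s)
                )
                out.append(rep.outputs["cat_equivalence"].median)
            return np.std(out)

        seeds = range(20, 26)
        assert medians(8000, seeds) < medians(300, seeds)


class TestBands:
    def test_shape_and_columns(self, band_table):
        assert list(band_table.columns) == [
            "n_cats", "q2p5", "q16", "q50", "q84", "q97p5",
        ]
        assert len(band_table) == 31

    def test_quantile_columns_ordered_and_nonincreasing(self, band_table):
        cols = ["q2p5", "q16", "q50", "q84", "q97p5"]
        arr = band_table[cols].to_numpy()
        assert (np.diff(arr, axis=1) >= -1e-9).all()      # nested quantiles
        assert (np.diff(arr, axis=0) <= 1e-9).all()       # negative slope
        assert (arr >= 0).all()

    def test_intercept_matches_scalar_summary(self, pset_split, small_plan, band_table):
        report = mt.monte_carlo_summary(pset_split.specs, small_plan)
        cr = report.outputs["critical_rats"]
        row = band_table.iloc[0]
        assert row["n_cats"] == 0
        assert row["q50"] == pytest.approx(cr.median, rel=1e-9)
        assert row["q2p5"] == pytest.approx(cr.ci95[0], rel=1e-9)
        assert row["q97p5"] == pytest.approx(cr.ci95[1], rel=1e-9)

    def test_zero_cv_collapses_to_threshold_line(self, pset_split, rates_split):
        plan = mt.SamplingPlan(n_draws=64, seed=3, cv_default=0.0)
        grid = np.arange(0.0, 40.0, 4.0)
        table = mt.phase_space_bands(pset_split.specs, plan, grid)
        line = mt.threshold_line(pset_split.demography, rates_split, grid)
        for col in ("q2p5", "q50", "q97p5"):
            np.testing.assert_allclose(table[col].to_numpy(), line, rtol=1e-12)

    def test_empty_or_negative_grid_rejected(self, pset, small_plan):
        with pytest.raises(ValueError):
            mt.phase_space_bands(pset.specs, small_plan, [])
        with pytest.raises(ValueError):
            mt.phase_space_bands(pset.specs, small_plan, [-1.0, 2.0])


class TestClassification:
    def test_origin_is_strong_increase(self, band_table):
        label = mt.classify_scenario(band_table, mt.PredatorScenario(0, 0))
        assert label == "increase >97.5%"

    def test_far_above_all_curves_is_strong_decline(self, band_table):
        label = mt.classify_scenario(band_table, mt.PredatorScenario(10, 1e6))
        assert label == "decline >97.5%"

    def test_point_on_median_takes_decline_side(self, band_table):
        cats = 10.0
        median_at = float(
            np.interp(cats, band_table["n_cats"], band_table["q50"])
        )
        label = mt.classify_scenario(
            band_table, mt.PredatorScenario(cats, median_at)
        )
        assert label == "decline 50-84%"

    def test_labels_ordered_with_rat_abundance(self, band_table):
        cats = 5.0
        rats_grid = np.linspace(0, 6000, 40)
        labels = [
            mt.classify_scenario(band_table, mt.PredatorScenario(cats, r))
            for r in rats_grid
        ]
        idx = [mt.REGION_LABELS.index(l) for l in labels]
        assert all(a >= b for a, b in zip(idx, idx[1:]))  # risk never decreases
        assert "decline >97.5%" in labels
        assert len(set(labels)) >= 4

    def test_extrapolation_refused(self, band_table):
        with pytest.raises(ValueError):
            mt.classify_scenario(band_table, mt.PredatorScenario(1e4, 10))
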