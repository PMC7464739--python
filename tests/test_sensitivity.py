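"""Tornado, ISER plane and probabilistic sensitivity machinery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hccseq import (
    PopulationProfile,
    SimConfig,
    TornadoVariable,
    WeibullParams,
    fit_meta_regression,
    gen_trial_catalog,
    one_way_tornado,
    probabilistic_analysis,
    profile_to_scale_shift,
    two_way_iser_plane,
)
from hccseq.sensitivity import _apply_variable, default_psa_ranges
from hccseq.synthetic_data import DEFAULT_CATALOG_COEFFICIENTS, default_trial_catalog


@pytest.fixture(scope="module")
def model():
    return fit_meta_regression(default_trial_catalog())


class TestMetaRegression:
    def test_noiseless_exact_recovery(self):
        model = fit_meta_regression(gen_trial_catalog(20, noise_sd=0.0, seed=1))
        np.testing.assert_allclose(model.coefficients, DEFAULT_CATALOG_COEFFICIENTS, atol=1e-8)

    def test_duplicated_rows_with_equal_weights_identical_fit(self):
        catalog = gen_trial_catalog(12, noise_sd=0.3, seed=2)
        catalog["n"] = 500
        doubled = pd.concat([catalog, catalog], ignore_index=True)
        a, b = fit_meta_regression(catalog), fit_meta_regression(doubled)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-10)

    def test_slope_coverage_over_seeds(self):
        """±2SE covers each generating slope in >= 90% of seeded replicates."""
        truth = np.asarray(DEFAULT_CATALOG_COEFFICIENTS)
        hits = np.zeros(4)
        n_rep = 100
        for seed in range(n_rep):
            model = fit_meta_regression(gen_trial_catalog(50, noise_sd=0.5, seed=seed))
            hits += np.abs(model.coefficients[1:] - truth[1:]) <= 2 * model.se[1:]
        assert np.all(hits / n_rep >= 0.90)

    def test_collinear_columns_named_in_error(self):
        catalog = gen_trial_catalog(15, noise_sd=0.1, seed=3)
        catalog["prev_hcv"] = catalog["prev_hbv"]
        with pytest.raises(ValueError, match="prev_hbv.*prev_hcv|prev_hcv.*prev_hbv"):
            fit_meta_regression(catalog)

    def test_too_few_trials_rejected(self):
        catalog = gen_trial_catalog(10, seed=4).head(5)
        with pytest.raises(ValueError, match=">= 6"):
            fit_meta_regression(catalog)


class TestScaleShift:
    def test_identity_when_profiles_equal(self, model):
        base = WeibullParams(12.0, 1.18)
        profile = PopulationProfile()
        shifted = profile_to_scale_shift(model, profile, profile, base)
        assert shifted == base

    def test_doubled_prediction_doubles_scale_and_median(self):
        # a synthetic model with only an intercept-free HBV effect
        from hccseq.sensitivity import MetaRegModel

        model = MetaRegModel(
            coefficients=np.array([4.0, 4.0, 0, 0, 0]),
            cov=np.eye(5), se=np.ones(5), n_trials=10, weights=np.ones(10),
        )
        baseline = PopulationProfile(hbv=0.0)
        varied = PopulationProfile(hbv=1.0)  # prediction 4 -> 8
        base = WeibullParams(10.0, 1.3)
        shifted = profile_to_scale_shift(model, baseline, varied, base)
        assert shifted.scale == pytest.approx(20.0)
        assert shifted.shape == base.shape
        assert shifted.median == pytest.approx(2 * base.median)

    def test_all_quantiles_shift_proportionally(self, model):
        from hccseq import weibull_quantile

        base = WeibullParams(9.75, 1.21)
        baseline = PopulationProfile()
        varied = baseline.replace(hbv=0.2)
        shifted = profile_to_scale_shift(model, baseline, varied, base)
        factor = shifted.scale / base.scale
        for p in (0.1, 0.5, 0.9):
            assert weibull_quantile(shifted, p) == pytest.approx(
                factor * weibull_quantile(base, p)
            )


class TestTornado:
    def test_zero_slope_variable_zero_width(self, model, strategy_for):
        cfg = SimConfig(n_patients=400, seed=30)
        bars = one_way_tornado(
            strategy_for("Lenvatinib", "Nivolumab"),
            strategy_for("Sorafenib", "Nivolumab"),
            [TornadoVariable("male"), TornadoVariable("hbv")],
            cfg,
            model,
        )
        male = bars.loc[bars["variable"] == "male"].iloc[0]
        assert male["width"] == 0.0
        assert bars.iloc[0]["variable"] == "hbv"  # wider bar sorted first

    def test_high_bound_capped_at_one(self, model, strategy_for):
        # baseline MaVI/EHD prevalence 0.88: a +30-point shift caps at 1.00
        strat = strategy_for("Lenvatinib", "Nivolumab")
        var = TornadoVariable("mavi_ehd")
        baseline = PopulationProfile()
        applied = _apply_variable(var, strat, model, baseline, value_is_high=True)
        explicit = profile_to_scale_shift(
            model, baseline, baseline.replace(mavi_ehd=1.0), strat.first_line.ttev
        )
        assert applied.first_line.ttev == explicit

    def test_parameter_bars_use_explicit_bounds(self, model, strategy_for):
        strat = strategy_for("Lenvatinib", "Nivolumab")
        var = TornadoVariable("nivo scale", kind="scale", target="second", low=20.0, high=26.0)
        hi = _apply_variable(var, strat, model, PopulationProfile(), True)
        lo = _apply_variable(var, strat, model, PopulationProfile(), False)
        assert hi.second_line.ttev.scale == 26.0
        assert lo.second_line.ttev.scale == 20.0
        assert hi.second_line.ttev.shape == strat.second_line.ttev.shape

    def test_influential_factors_have_wide_bars(self, model, strategy_for):
        cfg = SimConfig(n_patients=1000, seed=31)
        variables = [
            TornadoVariable(v) for v in ("hbv", "hcv", "mavi_ehd", "ecog1", "male", "asian")
        ]
        bars = one_way_tornado(
            strategy_for("Lenvatinib", "Nivolumab"),
            strategy_for("Sorafenib", "Nivolumab"),
            variables,
            cfg,
            model,
        )
        top = set(bars.head(4)["variable"])
        assert "mavi_ehd" in top
        assert {"male", "asian"}.isdisjoint(top)


class TestISERPlane:
    def test_favored_fraction_monotone_in_threshold(self):
        fracs = [
            two_way_iser_plane((3.8, 11.8), (1e-6, 0.5), threshold=t).favored_fraction
            for t in (5, 15, 30, 60, 120)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_dominant_region_always_favored(self):
        plane = two_way_iser_plane((-5.0, -0.1), (0.01, 0.5), threshold=30.0)
        assert plane.favored_fraction == 1.0

    def test_matches_closed_form_area(self):
        # fraction of the rectangle below the line dsae = thr * lyg
        s_lo, s_hi, l_hi, thr = 3.8, 11.8, 0.5, 30.0
        plane = two_way_iser_plane((s_lo, s_hi), (1e-9, l_hi), threshold=thr, grid=401)
        ls = np.linspace(1e-9, l_hi, 200_001)
        exact = np.trapezoid(np.clip((thr * ls - s_lo) / (s_hi - s_lo), 0, 1), ls) / l_hi
        assert plane.favored_fraction == pytest.approx(exact, abs=0.01)

    def test_high_lyg_high_sae_quadrant_more_favorable_than_low_low(self):
        plane = two_way_iser_plane((3.8, 11.8), (1e-6, 0.5), threshold=30.0)
        q = plane.quadrant_fractions
        assert q["high_lyg_high_sae"] > q["low_lyg_low_sae"]

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError):
            two_way_iser_plane((1.0, 1.0), (0.0, 0.5))
        with pytest.raises(ValueError):
            two_way_iser_plane((0.0, 4.0), (0.0, 0.5), threshold=0.0)


class TestProbabilisticAnalysis:
    def test_strategy_vs_itself_exceedance_half(self, model, strategy_for):
        strat = strategy_for("Lenvatinib", "Nivolumab")
        cfg = SimConfig(n_patients=500, seed=40)
        out = probabilistic_analysis(
            model,
            default_psa_ranges(default_trial_catalog()),
            [strat],
            strat,
            cfg,
            n_draws=60,
        )
        assert out.loc[0, "exceedance"] == pytest.approx(0.5, abs=0.2)

    def test_degenerate_ranges_reproduce_base_ordering(self, model, strategy_for):
        baseline = PopulationProfile()
        point_ranges = {
            "hbv": (baseline.hbv, baseline.hbv),
            "hcv": (baseline.hcv, baseline.hcv),
            "mavi_ehd": (baseline.mavi_ehd, baseline.mavi_ehd),
            "ecog1": (baseline.ecog1, baseline.ecog1),
        }
        cfg = SimConfig(n_patients=1000, seed=41)
        out = probabilistic_analysis(
            model,
            point_ranges,
            [strategy_for("Lenvatinib", "Nivolumab")],
            strategy_for("Sorafenib", "Ramucirumab"),
            cfg,
            n_draws=25,
        )
        assert out.loc[0, "exceedance"] >= 0.95

    def test_clearly_better_strategy_wins_nearly_always(self, model, strategy_for):
        cfg = SimConfig(n_patients=1000, seed=42)
        out = probabilistic_analysis(
            model,
            default_psa_ranges(default_trial_catalog()),
            [strategy_for("Lenvatinib", "Nivolumab")],
            strategy_for("Sorafenib", "Nivolumab"),
            cfg,
            n_draws=40,
        )
        assert out.loc[0, "exceedance"] >= 0.9

    def test_invalid_ranges_rejected(self, model, strategy_for):
        strat = strategy_for("Lenvatinib", "Nivolumab")
        with pytest.raises(ValueError):
            probabilistic_analysis(
                model, {"hbv": (0.5, 1.2)}, [strat], strat, SimConfig(), n_draws=5
            )
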