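"""Mixed-model geometric means, driver effects, variability, and R²."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from congoflux.fluxstats import (
    TransformSpec,
    between_chamber_variability,
    fit_driver_model,
    fit_geometric_mean_model,
    intra_annual_variability,
    nakagawa_r2,
    percent_change,
    wfps_from_vwc,
)
from congoflux.synth import PanelSimSpec, generate_flux_panel


class TestWfps:
    def test_hand_examples(self):
        assert wfps_from_vwc(0.0, 1.325) == 0.0
        # BD 1.325 / PD 2.65 -> porosity 0.5
        assert wfps_from_vwc(0.30, 1.325) == pytest.approx(60.0, rel=1e-12)
        assert wfps_from_vwc(0.5, 1.325) == pytest.approx(100.0, rel=1e-12)

    def test_zero_porosity_rejected(self):
        with pytest.raises(ValueError):
            wfps_from_vwc(0.3, 2.65)
        with pytest.raises(ValueError):
            wfps_from_vwc(1.2, 1.3)


def toy_panel(chamber_fluxes: dict[str, list[float]], dates=None) -> pd.DataFrame:
    rows = []
    for chamber, fluxes in chamber_fluxes.items():
        for i, f in enumerate(fluxes):
            d = dates[i] if dates else f"2018-01-{i + 1:02d}"
            rows.append(
                {"site": "s", "forest_type": "lowland", "chamber_id": chamber, "date": d, "flux": f}
            )
    return pd.DataFrame(rows)


class TestVariability:
    def test_chamber_means_1_2_3(self):
        panel = toy_panel({"a": [0.5, 1.5], "b": [2.0, 2.0], "c": [2.5, 3.5]})
        v = between_chamber_variability(panel)
        assert v.variance == pytest.approx(1.0)
        assert v.sd == pytest.approx(1.0)
        assert v.cv == pytest.approx(0.5)

    def test_identical_chambers_zero_variance(self):
        panel = toy_panel({"a": [2.0], "b": [2.0], "c": [2.0]})
        assert between_chamber_variability(panel).variance == 0.0

    def test_permutation_invariance(self):
        panel = toy_panel({"a": [1.0], "b": [2.0], "c": [3.0]})
        shuffled = panel.sample(frac=1, random_state=3)
        assert between_chamber_variability(shuffled).variance == pytest.approx(
            between_chamber_variability(panel).variance
        )

    def test_single_chamber_signalled(self):
        with pytest.raises(ValueError, match=">= 2 chambers"):
            between_chamber_variability(toy_panel({"a": [1.0, 2.0]}))

    def test_weekly_means_pooled_across_years(self):
        # same ISO week in different years lands in one class
        panel = toy_panel(
            {"a": [1.0, 3.0, 2.0, 4.0]},
            dates=["2018-01-02", "2019-01-02", "2018-06-05", "2019-06-04"],
        )
        v = intra_annual_variability(panel)
        # weekly means: week 1 -> 2.0, week 23 -> 3.0
        assert v.n_groups == 2
        assert v.variance == pytest.approx(np.var([2.0, 3.0], ddof=1))

    def test_single_week_signalled(self):
        with pytest.raises(ValueError, match="weeks"):
            intra_annual_variability(toy_panel({"a": [1.0]}, dates=["2018-01-02"]))


class TestTransforms:
    def test_log_positive_rejects_nonpositive_naming_rows(self):
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            TransformSpec("log_positive").apply(np.array([1.0, -2.0, 3.0]))

    def test_negate_log_round_trip(self):
        t = TransformSpec("negate_log")
        v = np.array([-1.0, -3.5])
        assert t.inverse(t.apply(v)) == pytest.approx(v)

    def test_shifted_log_round_trip(self):
        t = TransformSpec("shifted_log", shift=5.0)
        v = np.array([-4.0, 0.0, 10.0])
        assert t.inverse(t.apply(v)) == pytest.approx(v)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec("boxcox")


class TestGeometricMeanModel:
    def test_constant_panel_returns_constant_exactly(self):
        panel = toy_panel({"a": [2.5] * 4, "b": [2.5] * 4})
        res = fit_geometric_mean_model(panel, TransformSpec("log_positive"))
        assert res.geometric_mean == pytest.approx(2.5, rel=1e-12)
        assert res.ci_low == res.ci_high == res.geometric_mean
        assert all(v == 0 for v in res.variance_components.values())

    def test_all_negative_panel_under_negate_log(self):
        # geometric mean of an uptake panel is minus the gm of magnitudes
        spec = PanelSimSpec(true_median=-3.52, sign_regime="negative", n_dates=30, seed=5)
        panel = generate_flux_panel(spec)
        res = fit_geometric_mean_model(panel, TransformSpec("negate_log"))
        mirrored = panel.copy()
        mirrored["flux"] = -mirrored["flux"]
        res_pos = fit_geometric_mean_model(mirrored, TransformSpec("log_positive"))
        assert res.geometric_mean == pytest.approx(-res_pos.geometric_mean, rel=1e-9)
        assert res.ci_low < res.geometric_mean < res.ci_high

    @pytest.mark.parametrize("seed", [9, 13])
    def test_intercept_se_matches_balanced_design_closed_form(self, seed):
        # for a balanced crossed design the GLS intercept variance is
        # sigma_c^2/n_c + sigma_d^2/n_d + sigma_e^2/N; with zero fitted
        # components this is the plain log-scale sample-mean SE
        n_c, n_d = 5, 40
        spec = PanelSimSpec(
            true_median=2.0,
            sd_chamber=0.0,
            sd_date=0.0,
            sd_residual=0.4,
            n_chambers=n_c,
            n_dates=n_d,
            seed=seed,
        )
        panel = generate_flux_panel(spec)
        res = fit_geometric_mean_model(panel, TransformSpec("log_positive"))
        vc = res.variance_components
        closed_form = np.sqrt(
            vc["chamber"] / n_c + vc["date"] / n_d + vc["residual"] / (n_c * n_d)
        )
        assert res.intercept_se == pytest.approx(closed_form, rel=0.02)
        y = np.log(panel["flux"].to_numpy())
        assert res.intercept == pytest.approx(np.mean(y), abs=0.02)
        if vc["chamber"] == 0.0 and vc["date"] == 0.0:
            sample_mean_se = np.std(y, ddof=1) / np.sqrt(y.size)
            assert res.intercept_se == pytest.approx(sample_mean_se, rel=0.02)

    def test_shift_invariance_of_shifted_log_estimate(self):
        spec = PanelSimSpec(
            true_median=1.0, sign_regime="mixed", shift=3.0, n_dates=30, seed=21
        )
        panel = generate_flux_panel(spec)
        res = fit_geometric_mean_model(panel, TransformSpec("shifted_log", shift=3.0))
        moved = panel.copy()
        moved["flux"] = moved["flux"] + 2.0
        res2 = fit_geometric_mean_model(moved, TransformSpec("shifted_log", shift=1.0))
        assert res2.geometric_mean - 2.0 == pytest.approx(res.geometric_mean, rel=1e-6)

    def test_variance_components_recovered_in_large_panel(self):
        spec = PanelSimSpec(
            true_median=1.56,
            sd_chamber=0.4,
            sd_date=0.3,
            sd_residual=0.5,
            n_chambers=30,
            n_dates=80,
            seed=3,
        )
        res = fit_geometric_mean_model(generate_flux_panel(spec), TransformSpec("log_positive"))
        assert res.variance_components["chamber"] == pytest.approx(0.16, rel=0.5)
        assert res.variance_components["date"] == pytest.approx(0.09, rel=0.5)
        assert res.variance_components["residual"] == pytest.approx(0.25, rel=0.2)
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1


class TestDriverModel:
    def test_known_temperature_effect_recovered(self):
        spec = PanelSimSpec(
            true_median=1.56,
            beta_temp=0.05,
            sd_chamber=0.1,
            sd_date=0.0,
            sd_residual=0.2,
            n_chambers=10,
            n_dates=100,
            seed=17,
        )
        panel = generate_flux_panel(spec)
        res = fit_driver_model(panel, TransformSpec("log_positive"))
        # (e^0.05 - 1)*100 = 5.127% per °C
        assert res.percent_changes["soil_temperature"] == pytest.approx(5.127, abs=1.0)

    def test_single_chamber_reduces_to_ols(self):
        spec = PanelSimSpec(
            true_median=1.0, beta_temp=0.05, sd_chamber=0.0, n_chambers=1, n_dates=60, seed=23
        )
        panel = generate_flux_panel(spec)
        res = fit_driver_model(panel, TransformSpec("log_positive"))
        df = panel.copy()
        df["_y"] = np.log(df["flux"])
        ols = smf.ols("_y ~ soil_temperature + wfps", data=df).fit()
        assert res.fixed_effects["soil_temperature"][0] == pytest.approx(
            ols.params["soil_temperature"], rel=1e-8
        )
        assert "single chamber" in " ".join(res.notes)

    def test_constant_covariate_flagged_non_estimable(self):
        spec = PanelSimSpec(true_median=1.0, n_chambers=3, n_dates=20, seed=2)
        panel = generate_flux_panel(spec)
        panel["wfps"] = 55.0
        res = fit_driver_model(panel, TransformSpec("log_positive"))
        assert any("non-estimable" in n for n in res.notes)
        assert "wfps" not in res.percent_changes

    def test_zero_effect_ci_covers_zero_in_most_replicates(self):
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            spec = PanelSimSpec(
                true_median=1.0,
                beta_temp=0.0,
                sd_chamber=0.2,
                sd_date=0.0,
                sd_residual=0.4,
                n_chambers=4,
                n_dates=20,
                seed=1000 + rep,
            )
            res = fit_driver_model(generate_flux_panel(spec), TransformSpec("log_positive"))
            est, se = res.fixed_effects["soil_temperature"]
            if est - 1.96 * se <= 0.0 <= est + 1.96 * se:
                covered += 1
        assert covered / n_rep >= 0.90


class TestEffectScaling:
    def test_percent_change_examples(self):
        assert percent_change(0.0) == 0.0
        assert percent_change(np.log(2.0)) == pytest.approx(100.0, rel=1e-12)
        assert percent_change(-0.10536) == pytest.approx(-10.0, abs=1e-3)

    def test_nakagawa_r2_limits(self):
        r2m, r2c = nakagawa_r2(0.0, 0.3, 0.7)
        assert r2m == 0.0
        assert r2c == pytest.approx(0.3)
        r2m, r2c = nakagawa_r2(1.0, 0.0, 0.0)
        assert r2m == r2c == 1.0
        with pytest.raises(ValueError):
            nakagawa_r2(0.0, 0.0, 0.0)

    def test_nakagawa_r2_matches_plug_in_oracle_in_simulation(self):
        spec = PanelSimSpec(
            true_median=1.0,
            beta_temp=0.1,
            sd_chamber=0.3,
            sd_date=0.0,
            sd_residual=0.4,
            n_chambers=12,
            n_dates=80,
            seed=31,
        )
        panel = generate_flux_panel(spec)
        res = fit_driver_model(panel, TransformSpec("log_positive"))
        var_f = 0.1**2 * np.var(panel["soil_temperature"])  # true fixed-predictor variance
        expected = var_f / (var_f + 0.3**2 + 0.4**2)
        assert res.r2_marginal == pytest.approx(expected, rel=0.25)
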