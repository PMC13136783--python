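"""Effect arithmetic, scales, bootstrap and stratification."""

import numpy as np
import pandas as pd
import pytest

from droughtlegacy import aridity_class, bootstrap_ci, compute_effects, \
    detect_events, effect_for_event, land_cover_group, mean_window_gpp, \
    to_anomaly
from droughtlegacy.effects import site_mean_gpp, stratified_estimates
from droughtlegacy.events import build_windows

from conftest import make_site


def windows_for(rec):
    evs = detect_events(rec, "PDSI")
    return build_windows(evs, rec)


class TestMeanWindowGpp:
    def test_arithmetic_mean(self):
        rec = make_site([0] * 8, gpp=[0, 0, 0, 0, 0, 0, 100, 120],
                        years=range(1, 9))
        assert mean_window_gpp({7, 8}, rec) == pytest.approx(110.0)

    def test_empty_set_is_missing(self):
        rec = make_site([0, 0])
        assert np.isnan(mean_window_gpp([], rec))

    def test_single_year(self):
        rec = make_site([0, 0], gpp=[50.0, 70.0])
        assert mean_window_gpp([2], rec) == pytest.approx(70.0)


class TestEffectForEvent:
    def rec(self):
        # event years 5-6; pre 2-4; post 7-10
        gpp = [100, 100, 100, 100, 90, 90, 95, 95, 95, 95]
        return make_site([0, 0, 0, 0, -4, -4, 0, 0, 0, 0], gpp=gpp)

    def test_baseline_deltas(self):
        rec = self.rec()
        eff = effect_for_event(windows_for(rec)[0], rec, method="baseline")
        assert eff.delta_dir == pytest.approx(-10.0)
        assert eff.delta_lag == pytest.approx(-5.0)

    def test_missing_pre_propagates(self):
        rec = make_site([-4, 0, 0, 0, 0], gpp=[90, 95, 95, 95, 95])
        w = windows_for(rec)[0]
        eff = effect_for_event(w, rec, method="baseline")
        assert np.isnan(eff.delta_dir) and np.isnan(eff.delta_lag)
        # counterfactual legacy remains computable without predrought data
        eff_cf = effect_for_event(w, rec, method="counterfactual",
                                  expected_supplier=lambda s, y: 97.0)
        assert np.isnan(eff_cf.delta_dir)
        assert eff_cf.delta_lag == pytest.approx(95.0 - 97.0)

    def test_counterfactual_identity_when_predictions_match(self):
        rec = self.rec()
        lut = dict(zip(rec["year"], rec["gpp"]))
        eff = effect_for_event(windows_for(rec)[0], rec,
                               method="counterfactual",
                               expected_supplier=lambda s, y: lut[y])
        assert eff.delta_lag == pytest.approx(0.0)

    def test_horizon_cumulative_means(self):
        # anomaly-scale post values -10,-5,0,1 with expected 0
        gpp = [0, 0, 0, 10, -10, -5, 0, 1]
        rec = make_site([0, 0, 0, -4, 0, 0, 0, 0], gpp=gpp)
        w = windows_for(rec)[0]
        expected = {1: -10.0, 2: -7.5, 3: -5.0, 4: -3.5}
        for k, want in expected.items():
            eff = effect_for_event(w, rec, method="counterfactual",
                                   expected_supplier=lambda s, y: 0.0,
                                   horizon=k)
            assert eff.delta_lag == pytest.approx(want)

    def test_relative_scale_division_and_guard(self):
        rec = self.rec()
        w = windows_for(rec)[0]
        eff = effect_for_event(w, rec, scale="relative", site_mean=1000.0)
        assert eff.delta_dir == pytest.approx(-10.0 / 1000.0)
        bad = effect_for_event(w, rec, scale="relative", site_mean=0.0)
        assert np.isnan(bad.delta_dir)


class TestAnomaly:
    def test_centering(self):
        rec = make_site([0, 0, 0], gpp=[100, 120, 80])
        out = to_anomaly(rec)
        assert list(out["gpp"]) == [0.0, 20.0, -20.0]

    def test_all_equal_gives_zero(self):
        rec = make_site([0, 0], gpp=[100, 100])
        assert (to_anomaly(rec)["gpp"] == 0).all()

    def test_delta_dir_invariant_under_centering(self):
        rng = np.random.default_rng(5)
        rec = make_site([0, 0, 0, -4, -4, 0, 0, 0, 0, 0],
                        gpp=rng.uniform(500, 1500, 10))
        wins = windows_for(rec)
        eff_abs = compute_effects(rec, wins, method="baseline")
        eff_anom = compute_effects(to_anomaly(rec), wins, method="baseline",
                                   scale="anomaly")
        np.testing.assert_allclose(eff_abs["delta_dir"], eff_anom["delta_dir"],
                                   atol=1e-9)
        np.testing.assert_allclose(eff_abs["delta_lag"], eff_anom["delta_lag"],
                                   atol=1e-9)


class TestBootstrap:
    def test_degenerate_constant_values(self):
        med, lo, hi, sig = bootstrap_ci([3.0] * 10, seed=0)
        assert (med, lo, hi, sig) == (3.0, 3.0, 3.0, True)

    def test_single_value(self):
        med, lo, hi, sig = bootstrap_ci([-2.0], seed=0)
        assert (med, lo, hi) == (-2.0, -2.0, -2.0)
        assert sig

    def test_symmetric_values_not_significant(self):
        vals = np.random.default_rng(8).normal(0.0, 1.0, 400)
        med, lo, hi, sig = bootstrap_ci(vals, seed=1)
        assert lo < 0 < hi and not sig

    def test_seed_determinism(self):
        vals = np.random.default_rng(2).normal(1.0, 1.0, 50)
        assert bootstrap_ci(vals, seed=9) == bootstrap_ci(vals, seed=9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])

    def test_ci_width_shrinks_like_sqrt_n(self):
        """log(CI width) vs log(n) slope ~ -1/2 for i.i.d. effects."""
        rng = np.random.default_rng(3)
        ns = [25, 100, 400, 1600]
        widths = []
        for n in ns:
            w = [bootstrap_ci(rng.normal(0, 1, n), seed=r)[2]
                 - bootstrap_ci(rng.normal(0, 1, n), seed=r)[1]
                 for r in range(5)]
            widths.append(np.mean(w))
        slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestStratification:
    @pytest.mark.parametrize("ai,label", [
        (0.01, "hyper_arid"), (0.05, "arid"), (0.1, "arid"),
        (0.2, "semi_arid"), (0.3, "semi_arid"), (0.5, "dry_sub_humid"),
        (0.64, "dry_sub_humid"), (0.65, "humid"), (1.5, "humid"),
    ])
    def test_aridity_classes(self, ai, label):
        assert aridity_class(ai) == label

    @pytest.mark.parametrize("igbp,group", [
        ("ENF", "needleleaf_forests"), ("DNF", "needleleaf_forests"),
        ("EBF", "broadleaf_forests"), ("DBF", "broadleaf_forests"),
        ("MF", "mixed_forests"), ("CSH", "shrublands"), ("OSH", "shrublands"),
        ("WSA", "savannas"), ("SAV", "savannas"), ("GRA", "grasslands"),
    ])
    def test_land_cover_groups(self, igbp, group):
        assert land_cover_group(igbp) == group

    def test_cropland_rejected(self):
        with pytest.raises(ValueError):
            land_cover_group("CRO")

    def test_global_median_of_opposite_strata(self):
        effects = pd.DataFrame({
            "site_id": ["A", "B"], "delta_dir": [-5.0, 5.0],
            "delta_lag": [np.nan, np.nan]})
        attrs = pd.DataFrame({"site_id": ["A", "B"], "ai": [0.1, 0.8],
                              "igbp": ["ENF", "GRA"]})
        est = stratified_estimates(effects, attrs, strata="global",
                                   effect="dir", n_boot=100, seed=0)
        assert est.loc[0, "median"] == pytest.approx(0.0)
        assert est.loc[0, "n"] == 2

    def test_empty_strata_omitted(self):
        effects = pd.DataFrame({"site_id": ["A"], "delta_dir": [-5.0],
                                "delta_lag": [np.nan]})
        attrs = pd.DataFrame({"site_id": ["A"], "ai": [0.1],
                              "igbp": ["ENF"]})
        est = stratified_estimates(effects, attrs, strata="aridity",
                                   effect="dir", n_boot=50, seed=0)
        assert list(est["stratum"]) == ["arid"]

    def test_ci_brackets_median_and_significance_rule(self):
        rng = np.random.default_rng(4)
        effects = pd.DataFrame({
            "site_id": [f"S{i}" for i in range(60)],
            "delta_dir": rng.normal(-50, 10, 60),
            "delta_lag": rng.normal(0, 10, 60)})
        attrs = pd.DataFrame({"site_id": effects["site_id"],
                              "ai": 0.8, "igbp": "ENF"})
        for eff, want_sig in (("dir", True), ("lag", False)):
            est = stratified_estimates(effects, attrs, strata="global",
                                       effect=eff, n_boot=500, seed=2)
            row = est.iloc[0]
            assert row["ci_low"] <= row["median"] <= row["ci_high"]
            assert row["significant"] == want_sig
            assert row["significant"] == (not row["ci_low"] <= 0 <= row["ci_high"])


def test_site_mean_gpp_over_all_years():
    rec = make_site([0, 0, -4], gpp=[100.0, 200.0, 60.0])
    assert site_mean_gpp(rec).loc["S1"] == pytest.approx(120.0)
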