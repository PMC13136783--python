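"""Driver dataset assembly and stepwise additive-model behaviour."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from droughtlegacy import SimConfig, compute_effects, detect_events, \
    generate_sites, to_anomaly
from droughtlegacy.drivers import DriverDataset, assemble_driver_dataset, \
    fit_stepwise_gam
from droughtlegacy.events import build_windows_all
from droughtlegacy import gam

from conftest import make_site


def synthetic_dataset(n=400, seed=0, signal=True, n_candidates=20):
    """Craft a DriverDataset with known structure for stepwise tests."""
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_candidates)]
    df = pd.DataFrame({nm: rng.normal(size=n) for nm in names})
    df["land_cover"] = rng.choice(["ENF", "GRA", "DBF"], n)
    if signal:
        y = np.sin(2.0 * df["x0"]) + 0.8 * df["x1"] ** 2 + 0.9 * df["x2"]
        y = y + rng.normal(0, 1.0, n)
    else:
        y = rng.normal(size=n)
    df["response"] = (y - y.mean()) / y.std(ddof=1)
    return DriverDataset(data=df, response="response", continuous=names,
                         categorical=["land_cover"], target="lag",
                         n_dropped=0, standardization=None)


class TestAssembly:
    def one_event_table(self):
        # event year 5; pre 2-4; post 6-9
        t_vals = [9, 10, 11, 12, 20, 10, 12, 11, 13, 12]
        rec = make_site([0, 0, 0, 0, -4, 0, 0, 0, 0, 0],
                        gpp=[100.0, 110, 90, 100, 80, 95, 96, 97, 98, 99])
        rec["t"] = t_vals
        rec2 = rec.copy()
        rec2["site_id"] = "S2"
        rec2["t"] = [float(v) + 1 for v in t_vals]
        rec2["gpp"] = rec2["gpp"] * 1.1
        return pd.concat([rec, rec2], ignore_index=True)

    def build(self, target):
        table = self.one_event_table()
        ev = {str(s): detect_events(g, "PDSI")
              for s, g in table.groupby("site_id")}
        wins = build_windows_all(ev, table)
        eff = compute_effects(table, wins, method="baseline", horizon=4)
        return assemble_driver_dataset(eff, wins, table, target=target), eff

    def test_period_difference_arithmetic(self):
        ds, _ = self.build("lag")
        stats = ds.standardization.set_index("column")
        raw = ds.data["d_t"] * stats.loc["d_t", "sd"] + stats.loc["d_t", "mean"]
        # post T mean(10,12,11,13) = 11.5, pre mean(10,11,12) = 11 -> diff 0.5
        assert sorted(raw.round(9)) == [0.5, 0.5]
        focal = ds.data["t_focal"] * stats.loc["t_focal", "sd"] \
            + stats.loc["t_focal", "mean"]
        assert sorted(focal.round(9)) == [11.5, 12.5]

    def test_drought_period_means_for_dir_target(self):
        ds, _ = self.build("dir")
        stats = ds.standardization.set_index("column")
        focal = ds.data["t_focal"] * stats.loc["t_focal", "sd"] \
            + stats.loc["t_focal", "mean"]
        assert sorted(focal.round(9)) == [20.0, 21.0]

    def test_standardized_columns_are_z_scores(self):
        ds, _ = self.build("lag")
        for col in ["response"] + ds.continuous:
            vals = ds.data[col].to_numpy()
            assert abs(vals.mean()) < 1e-10
            if np.ptp(vals) > 0:
                assert abs(vals.std(ddof=1) - 1.0) < 1e-10

    def test_sample_sd_convention(self):
        from droughtlegacy.drivers import _standardize
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        _standardize(df, ["x"])
        assert list(df["x"]) == [-1.0, 0.0, 1.0]

    def test_target_sets_differ_on_direct_effect(self):
        ds_lag, _ = self.build("lag")
        ds_dir, _ = self.build("dir")
        assert "delta_gpp_dir" in ds_lag.continuous
        assert "delta_gpp_dir" not in ds_dir.continuous

    def test_events_with_missing_windows_dropped(self):
        table = self.one_event_table()
        table.loc[table["year"] < 5, "gpp"] = np.nan  # no predrought GPP
        ev = {str(s): detect_events(g, "PDSI")
              for s, g in table.groupby("site_id")}
        wins = build_windows_all(ev, table)
        eff = compute_effects(table, wins, method="baseline", horizon=4)
        ds = assemble_driver_dataset(eff, wins, table, target="lag")
        assert len(ds.data) == 0 and ds.n_dropped == 2


class TestStepwise:
    def test_true_drivers_recovered(self):
        fit = fit_stepwise_gam(synthetic_dataset(seed=1))
        assert {"x0", "x1", "x2"} <= set(fit.retained)
        assert sum(fit.importance.values()) == pytest.approx(100.0, abs=0.1)
        assert fit.max_concurvity < 0.8

    def test_pure_noise_retains_nothing(self):
        fit = fit_stepwise_gam(synthetic_dataset(seed=2, signal=False))
        assert fit.retained == []
        assert fit.empty

    def test_duplicated_predictor_removed_by_concurvity_guard(self):
        ds = synthetic_dataset(n=300, seed=3, n_candidates=3, signal=False)
        df = ds.data
        df["x_dup"] = df["x2"] + 1e-9 * np.random.default_rng(0).normal(
            size=len(df))
        df["response"] = (df["x2"] + 0.2 * np.random.default_rng(1).normal(
            size=len(df)))
        ds2 = DriverDataset(data=df, response="response",
                            continuous=["x2", "x_dup"], categorical=[],
                            target="lag", n_dropped=0, standardization=None)
        fit = fit_stepwise_gam(ds2)
        assert len({"x2", "x_dup"} & set(fit.retained)) == 1
        assert fit.max_concurvity < 0.8

    def test_terminates_within_candidate_count(self):
        ds = synthetic_dataset(seed=4, signal=False)
        fit = fit_stepwise_gam(ds)
        assert len(fit.history) <= len(ds.continuous) + 1

    def test_idempotent_refit_of_retained_set(self):
        ds = synthetic_dataset(seed=5)
        fit = fit_stepwise_gam(ds)
        ds2 = DriverDataset(data=ds.data, response="response",
                            continuous=[c for c in fit.retained
                                        if c != "land_cover"],
                            categorical=["land_cover"]
                            if "land_cover" in fit.retained else [],
                            target="lag", n_dropped=0, standardization=None)
        fit2 = fit_stepwise_gam(ds2)
        assert set(fit2.retained) == set(fit.retained)
        assert fit2.r2 == pytest.approx(fit.r2, abs=1e-9)

    def test_row_guard(self):
        with pytest.raises(ValueError, match="too few"):
            fit_stepwise_gam(synthetic_dataset(n=50, seed=6))

    def test_monotone_partial_effect_for_linear_dependence(self):
        """A positive linear driver has an increasing partial effect over
        the central 80% of its range."""
        ds = synthetic_dataset(n=500, seed=7, n_candidates=4, signal=False)
        df = ds.data
        df["response"] = df["x0"] + 0.3 * np.random.default_rng(2).normal(
            size=len(df))
        fit = fit_stepwise_gam(ds)
        assert "x0" in fit.retained
        grid = fit.partial_effects["x0"]
        lo, hi = np.quantile(df["x0"], [0.1, 0.9])
        central = grid[(grid["value"] >= lo) & (grid["value"] <= hi)]
        assert (np.diff(central["effect"]) > 0).all()


class TestImportance:
    def test_single_term_is_100(self):
        ds = synthetic_dataset(n=300, seed=8, n_candidates=1, signal=False)
        df = ds.data
        df["response"] = df["x0"] + 0.3 * np.random.default_rng(3).normal(
            size=len(df))
        fit = fit_stepwise_gam(ds)
        assert fit.retained == ["x0"]
        assert fit.importance["x0"] == pytest.approx(100.0)

    def test_two_equal_orthogonal_terms_split_evenly(self):
        rng = np.random.default_rng(9)
        n = 2000
        df = pd.DataFrame({"x0": rng.normal(size=n), "x1": rng.normal(size=n)})
        df["response"] = df["x0"] + df["x1"] + 0.5 * rng.normal(size=n)
        ds = DriverDataset(data=df, response="response",
                           continuous=["x0", "x1"], categorical=[],
                           target="lag", n_dropped=0, standardization=None)
        fit = fit_stepwise_gam(ds)
        assert fit.importance["x0"] == pytest.approx(50.0, abs=5.0)
        assert fit.importance["x1"] == pytest.approx(50.0, abs=5.0)

    def test_uniform_shares_when_no_variance_explained(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x0": rng.normal(size=200),
                           "x1": rng.normal(size=200)})
        df["y"] = rng.normal(size=200)
        fit = gam.fit_additive(df, "y", [gam.SmoothTerm("x0"),
                                         gam.SmoothTerm("x1")])
        fit.importance_raw = {"x0": 0.0, "x1": -0.01}
        with pytest.warns(UserWarning):
            shares = gam.importance_shares(fit)
        assert shares == {"x0": 50.0, "x1": 50.0}


def test_additive_fit_agrees_with_mgcv_regression_splines(tmp_path):
    """Independent oracle: mgcv with fixed-df regression splines should
    explain a comparable share of variance on the same data."""
    rng = np.random.default_rng(11)
    n = 300
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = np.sin(2 * x1) + 0.5 * x2**2 + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
    fit = gam.fit_additive(df, "y", [gam.SmoothTerm("x1"),
                                     gam.SmoothTerm("x2")])
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(mgcv))
        d <- read.csv("{csv}")
        m <- gam(y ~ s(x1, k=6, fx=TRUE) + s(x2, k=6, fx=TRUE), data=d)
        cat(summary(m)$dev.expl)
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    mgcv_r2 = float(out.stdout.strip().split()[-1])
    assert fit.r2 == pytest.approx(mgcv_r2, abs=0.03)
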