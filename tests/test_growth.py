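import math

import numpy as np
import pandas as pd
import pytest

from evotol import growth, synth
from evotol.validation import growth_window_oracle


def make_curve(mu=0.5, lag=2.0, od0=0.005, capacity=1.2, noise=0.0, seed=0,
               blank=0.0):
    t = np.arange(0.0, 48.0 + 1e-9, 1 / 6)
    od = synth.three_phase_od(t, mu, lag, od0, capacity) + blank
    if noise:
        od = od + np.random.default_rng(seed).normal(0, noise, od.shape)
    return growth.GrowthCurve("w", t, od)


class TestFitMuMax:
    def test_noiseless_exact_slope(self):
        curve = make_curve(mu=0.5)
        fit = growth.fit_mu_max(curve, growth.GrowthFitConfig(noise_sd=0.0))
        assert not fit.no_growth
        assert fit.mu_max == pytest.approx(0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_window_slope_matches_plain_regression(self):
        curve = make_curve(mu=0.4, noise=0.002, seed=1)
        cfg = growth.GrowthFitConfig(noise_sd=0.002)
        fit = growth.fit_mu_max(curve, cfg)
        i0, i1 = fit.window
        slope = np.polyfit(curve.time_h[i0:i1 + 1],
                           np.log(curve.od600[i0:i1 + 1]), 1)[0]
        assert fit.mu_max == pytest.approx(slope, rel=1e-10)

    def test_window_matches_exhaustive_oracle(self):
        cfg = growth.GrowthFitConfig(noise_sd=0.002)
        for seed in range(5):
            curve = make_curve(mu=0.3 + 0.1 * seed, noise=0.002, seed=seed)
            fit = growth.fit_mu_max(curve, cfg)
            assert fit.window == growth_window_oracle(curve, cfg)

    def test_flat_curve_is_no_growth(self):
        t = np.arange(0.0, 48.0, 1 / 6)
        od = np.full_like(t, 0.05) + np.random.default_rng(0).normal(0, 0.002, t.shape)
        fit = growth.fit_mu_max(growth.GrowthCurve("w", t, od), blank=0.05)
        assert fit.no_growth and fit.mu_max == 0.0 and fit.window is None

    def test_blank_subtraction_matters(self):
        curve = make_curve(mu=0.5, blank=0.05)
        fit = growth.fit_mu_max(curve, growth.GrowthFitConfig(noise_sd=0.0),
                                blank=0.05)
        assert fit.mu_max == pytest.approx(0.5, abs=1e-9)

    def test_unknown_selection_rule(self):
        curve = make_curve()
        with pytest.raises(ValueError):
            growth.fit_mu_max(curve, growth.GrowthFitConfig(selection="best"))


def test_growth_curve_validation():
    with pytest.raises(ValueError):
        growth.GrowthCurve("w", [0, 1, 2], [0.1, 0.2])
    with pytest.raises(ValueError):
        growth.GrowthCurve("w", [2, 1] + list(range(3, 13)), [0.1] * 12)


def test_fit_plate_recovers_planted_rates():
    truth = pd.DataFrame({"well": ["A1", "A2", "A3"], "mu": [0.25, 0.5, 0.75],
                          "lag_h": [1.0, 2.0, 3.0], "od0": [0.005] * 3,
                          "capacity": [1.2] * 3,
                          "strain": ["wt", "mut", "mut"],
                          "condition": ["ctl", "ctl", "trt"]})
    plate, plate_map = synth.gen_growth_plate(
        truth, synth.SimConfig(seed=4, noise_sd=0.002))
    fits = growth.fit_plate(plate, plate_map, growth.GrowthFitConfig(noise_sd=0.002))
    fits = fits.set_index("well")
    for rec in truth.itertuples(index=False):
        assert fits.loc[rec.well, "mu_max"] == pytest.approx(rec.mu, rel=0.02)
        assert fits.loc[rec.well, "strain"] == rec.strain
    assert "BLANK1" not in fits.index


def test_aggregate_fitness():
    fits = pd.DataFrame({"strain": ["m", "m", "r"], "condition": ["c", "c", "c"],
                         "mu_max": [0.4, 0.6, 0.5]})
    recs = {(r.strain, r.condition): r for r in growth.aggregate_fitness(fits)}
    m = recs[("m", "c")]
    assert m.mu_max == pytest.approx(0.5)
    assert m.se == pytest.approx(np.std([0.4, 0.6], ddof=1) / math.sqrt(2))
    assert m.n_replicates == 2
    assert math.isnan(recs[("r", "c")].se)


class TestScalarStats:
    def test_relative_fitness(self):
        assert growth.relative_fitness(0.6, 0.5) == pytest.approx(1.2)
        assert math.isnan(growth.relative_fitness(0.6, 0.0))

    def test_normalized_relative_fitness(self):
        assert growth.normalized_relative_fitness(0.9, 0.75) == pytest.approx(1.2)
        assert math.isnan(growth.normalized_relative_fitness(0.9, 0.0))

    def test_percent_relative_inhibition(self):
        assert growth.percent_relative_inhibition(0.5, 0.5) == 0.0
        assert growth.percent_relative_inhibition(0.3, 0.6) == pytest.approx(50.0)
        assert math.isnan(growth.percent_relative_inhibition(0.3, 0.0))

    def test_tolerance_improvement(self):
        assert growth.tolerance_improvement(2.0, 1.25) == pytest.approx(60.0)
        assert growth.tolerance_improvement(1.75, 1.25) == pytest.approx(40.0)
        with pytest.raises(ValueError):
            growth.tolerance_improvement(1.0, 0.0)

    def test_percent_change(self):
        assert growth.percent_change(1.5, 1.0) == pytest.approx(50.0)

    def test_specific_fluorescence(self):
        assert growth.specific_fluorescence(100.0, 0.5) == pytest.approx(200.0)
        assert math.isnan(growth.specific_fluorescence(100.0, 0.0))

    def test_mdh_activity(self):
        # dA/min / (epsilon * path * mass) with the default assay constants
        assert growth.mdh_activity(0.0622) == pytest.approx(
            0.0622 / (6.22 * 1.0 * 0.0045))
        with pytest.raises(ValueError):
            growth.AssayParams(epsilon_340=0.0)


def test_plate_io_roundtrip(tmp_path):
    long = pd.DataFrame({"well": ["A1"] * 3, "time_h": [0.0, 1.0, 2.0],
                         "od600": [0.1, 0.2, 0.4]})
    p = tmp_path / "plate.csv"
    long.to_csv(p, index=False)
    assert growth.read_plate_csv(p).equals(long)
    wide = pd.DataFrame({"time_h": [0.0, 1.0], "A1": [0.1, 0.2], "A2": [0.1, 0.3]})
    pw = tmp_path / "wide.csv"
    wide.to_csv(pw, index=False)
    out = growth.read_plate_csv(pw, layout="wide")
    assert set(out.columns) == {"well", "time_h", "od600"}
    assert len(out) == 4
    with pytest.raises(ValueError):
        growth.read_plate_csv(p, layout="wide")
    pm = tmp_path / "map.csv"
    pd.DataFrame({"well": ["A1"], "strain": ["wt"], "condition": ["ctl"],
                  "blank": [False]}).to_csv(pm, index=False)
    assert growth.read_plate_map(pm)["well"].tolist() == ["A1"]
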