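"""Plate ingestion, corrections and window-fitting tests, checked against
independent brute-force window-scan oracles."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from burdenkit.plate_assay import (
    Plate,
    PlateFormatError,
    PlateLayout,
    WellInfo,
    WellSeries,
    align_baselines,
    fit_max_growth_rate,
    fit_max_production_rate,
    fit_plate,
    read_plate,
    subtract_blanks,
    write_plate,
)
from burdenkit.synthdata import plate_to_frames


def _mini_plate(n_points=37, blank_level=0.04):
    """Three-well plate: two replicates of one strain plus a blank."""
    t = np.arange(n_points) * 10.0
    od = 0.05 * np.exp(0.015 * t)
    wells = {
        "A1": WellInfo("s1", "test", 1),
        "A2": WellInfo("s1", "test", 2),
        "A3": WellInfo(None, "blank", 1),
    }
    series = {
        "A1": WellSeries("A1", t, blank_level + od, {"GFP": 100 + 5 * t}),
        "A2": WellSeries("A2", t, blank_level + od + 0.01, {"GFP": 150 + 5 * t}),
        "A3": WellSeries("A3", t, np.full_like(t, blank_level), {"GFP": np.full_like(t, 100.0)}),
    }
    return Plate(PlateLayout("p1", wells, ["OD600", "GFP"]), series)


class TestReadWrite:
    def test_round_trip(self, tmp_path, default_plate):
        plate, _ = default_plate
        run, lay = tmp_path / "run.csv", tmp_path / "layout.csv"
        write_plate(plate, run, lay)
        back = read_plate(run, lay)
        for well in plate.wells:
            assert np.allclose(back.wells[well].od, plate.wells[well].od)
            for ch in plate.wells[well].channels:
                assert np.allclose(
                    back.wells[well].channels[ch], plate.wells[well].channels[ch]
                )

    def test_generator_output_parses_without_warnings(self, tmp_path, default_plate):
        plate, _ = default_plate
        run_df, lay_df = plate_to_frames(plate)
        run, lay = tmp_path / "run.csv", tmp_path / "layout.csv"
        run_df.to_csv(run, index=False)
        lay_df.to_csv(lay, index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = read_plate(run, lay)
        assert len(back.wells) == 96

    def test_layout_missing_well_rejected(self, tmp_path):
        run = tmp_path / "run.csv"
        lay = tmp_path / "layout.csv"
        pd.DataFrame(
            {"well": ["A1", "B9"], "time_min": [0, 0], "channel": ["OD600"] * 2,
             "value": [0.1, 0.1]}
        ).to_csv(run, index=False)
        pd.DataFrame(
            {"well": ["A1"], "strain": ["s"], "role": ["test"], "replicate": [1]}
        ).to_csv(lay, index=False)
        with pytest.raises(PlateFormatError, match="B9"):
            read_plate(run, lay)

    def test_duplicate_measurements_rejected(self, tmp_path):
        run = tmp_path / "run.csv"
        lay = tmp_path / "layout.csv"
        pd.DataFrame(
            {"well": ["A1", "A1"], "time_min": [0, 0], "channel": ["OD600"] * 2,
             "value": [0.1, 0.2]}
        ).to_csv(run, index=False)
        pd.DataFrame(
            {"well": ["A1"], "strain": ["s"], "role": ["test"], "replicate": [1]}
        ).to_csv(lay, index=False)
        with pytest.raises(PlateFormatError, match="duplicate"):
            read_plate(run, lay)


class TestCorrections:
    def test_blank_subtraction_zeroes_blank_identical_wells(self):
        plate = _mini_plate()
        for w in plate.wells.values():  # make every well equal the blank
            w.od = plate.wells["A3"].od.copy()
            w.channels["GFP"] = plate.wells["A3"].channels["GFP"].copy()
        out = subtract_blanks(plate)
        for w in out.wells.values():
            assert np.allclose(w.od, 0.0)
            assert np.allclose(w.channels["GFP"], 0.0)

    def test_constant_blank_shifts_everything(self):
        plate = _mini_plate(blank_level=0.04)
        out = subtract_blanks(plate)
        assert np.allclose(out.wells["A1"].od, plate.wells["A1"].od - 0.04)

    def test_no_blanks_is_an_error(self):
        plate = _mini_plate()
        del plate.layout.wells["A3"], plate.wells["A3"]
        with pytest.raises(PlateFormatError, match="blank"):
            subtract_blanks(plate)

    def test_generator_baseline_recovered(self, default_plate, default_config):
        """Blank subtraction removes the configured media background."""
        plate, _ = default_plate
        out = subtract_blanks(plate)
        resid = [out.wells[w].od[0] - default_config.od_init
                 for w, i in plate.layout.wells.items() if i.role != "blank"]
        # residuals at t=0: baseline offsets + noise, centered on zero
        assert abs(np.mean(resid)) < 2 * np.std(resid) / np.sqrt(len(resid)) + 5e-4

    def test_single_replicate_unchanged(self):
        plate = _mini_plate()
        del plate.layout.wells["A2"], plate.wells["A2"]
        out = align_baselines(plate)
        assert np.allclose(out.wells["A1"].od, plate.wells["A1"].od)

    def test_symmetric_offsets_equalized_and_grand_mean_conserved(self):
        plate = _mini_plate()
        sub = subtract_blanks(plate)
        mask = sub.wells["A1"].times <= 60.0
        grand_before = np.mean(
            [sub.wells[w].od[mask].mean() for w in ("A1", "A2")]
        )
        out = align_baselines(sub)
        m1 = out.wells["A1"].od[mask].mean()
        m2 = out.wells["A2"].od[mask].mean()
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert np.mean([m1, m2]) == pytest.approx(grand_before, abs=1e-12)

    def test_corrections_commute_with_global_constant(self):
        """Adding one constant to all wells changes nothing after blank
        subtraction + baseline alignment."""
        plate = _mini_plate()
        shifted = plate.copy()
        for w in shifted.wells.values():
            w.od = w.od + 0.123
            w.channels["GFP"] = w.channels["GFP"] + 7.0
        a = align_baselines(subtract_blanks(plate))
        b = align_baselines(subtract_blanks(shifted))
        for well in a.wells:
            assert np.allclose(a.wells[well].od, b.wells[well].od, atol=1e-12)
            assert np.allclose(
                a.wells[well].channels["GFP"], b.wells[well].channels["GFP"], atol=1e-9
            )

    def test_short_series_rejected(self):
        t = np.array([0.0, 10.0])
        plate = Plate(
            PlateLayout("p", {"A1": WellInfo("s", "test", 1), "A2": WellInfo("s", "test", 2)},
                        ["OD600"]),
            {"A1": WellSeries("A1", t, np.array([0.1, 0.2]), {}),
             "A2": WellSeries("A2", t, np.array([0.1, 0.2]), {})},
        )
        with pytest.raises(PlateFormatError, match="baseline window"):
            align_baselines(plate, window_min=5.0)


def _oracle_growth(times, od, window_pts=9, od_min=0.03):
    """Independent window-scan: nonlinear least squares via least_squares
    per eligible window, max r wins."""
    best = -np.inf
    for i in range(len(times) - window_pts + 1):
        if od[i] <= od_min:
            continue
        t = times[i : i + window_pts] - times[i]
        y = od[i : i + window_pts]
        res = least_squares(
            lambda p: p[0] * np.exp(p[1] * t) - y,
            x0=[max(y[0], 1e-6), 0.01],
            bounds=([0, 0], [np.inf, 1.0]),
            xtol=1e-12, ftol=1e-12,
        )
        if res.x[1] > best:
            best = res.x[1]
    return best


class TestGrowthFit:
    def test_noise_free_exponential_recovered(self):
        t = np.arange(37) * 10.0
        od = 0.005 * np.exp(0.02 * t)
        fit = fit_max_growth_rate(WellSeries("w", t, od, {}))
        assert fit.status == "ok"
        assert fit.r_max == pytest.approx(0.02, abs=1e-6 * 0.02)

    def test_logistic_curve_matches_brute_force_oracle(self):
        t = np.arange(37) * 10.0
        K, r, C0 = 1.0, 0.015, 0.01
        od = K * C0 * np.exp(r * t) / (K - C0 + C0 * np.exp(r * t))
        fit = fit_max_growth_rate(WellSeries("w", t, od, {}))
        oracle = _oracle_growth(t, od)
        assert fit.r_max == pytest.approx(oracle, rel=0.05)

    def test_no_growth_below_threshold(self):
        t = np.arange(37) * 10.0
        od = np.full_like(t, 0.02)
        fit = fit_max_growth_rate(WellSeries("w", t, od, {}))
        assert fit.status == "no_growth"

    def test_rate_invariant_to_od_scaling(self):
        t = np.arange(37) * 10.0
        rng = np.random.default_rng(0)
        od = 0.01 * np.exp(0.018 * t) + rng.normal(0, 0.002, t.size)
        a = fit_max_growth_rate(WellSeries("w", t, od, {}))
        b = fit_max_growth_rate(WellSeries("w", t, 5 * od, {}), od_min=0.15)
        assert b.r_max == pytest.approx(a.r_max, rel=1e-3)

    def test_matches_oracle_on_noisy_fixtures(self):
        rng = np.random.default_rng(7)
        t = np.arange(37) * 10.0
        for _ in range(5):
            r, C0 = rng.uniform(0.01, 0.02), rng.uniform(0.005, 0.02)
            od = C0 * np.exp(r * t) / (1 - C0 + C0 * np.exp(r * t)) + rng.normal(0, 0.003, t.size)
            fit = fit_max_growth_rate(WellSeries("w", t, od, {}))
            oracle = _oracle_growth(t, od)
            assert fit.r_max == pytest.approx(oracle, rel=1e-4)


def _oracle_production(times, od_fit, fvals, window_pts=9):
    """Independent per-window (F0, p) optimisation with frozen (C0, r)."""
    best = -np.inf
    for wf in od_fit.window_fits:
        i = wf.start
        t = times[i : i + window_pts] - wf.t0
        y = fvals[i : i + window_pts]
        res = least_squares(
            lambda q: q[0] + wf.C0 * (q[1] / wf.r) * (np.exp(wf.r * t) - 1) - y,
            x0=[y[0], 1.0],
            xtol=1e-13, ftol=1e-13,
        )
        if res.x[1] > best:
            best = res.x[1]
    return best


class TestProductionFit:
    def _well(self, p_of_t, r=0.02, C0=0.005, n=37):
        t = np.arange(n) * 10.0
        od = C0 * np.exp(r * t)
        # F(t) = int p(s) C(s) ds on a fine grid
        tf = np.linspace(0, t[-1], 20 * n)
        from scipy.integrate import cumulative_trapezoid

        F = cumulative_trapezoid(p_of_t(tf) * C0 * np.exp(r * tf), tf, initial=0.0)
        return WellSeries("w", t, od, {"GFP": np.interp(t, tf, F)})

    def test_constant_production_recovered(self):
        well = self._well(lambda t: np.full_like(t, 500.0))
        gfit = fit_max_growth_rate(well)
        p, F0 = fit_max_production_rate(well, gfit, "GFP")
        assert p == pytest.approx(500.0, rel=1e-3)

    def test_constant_fluorescence_gives_zero_rate(self):
        t = np.arange(37) * 10.0
        well = WellSeries("w", t, 0.005 * np.exp(0.02 * t), {"GFP": np.full_like(t, 800.0)})
        gfit = fit_max_growth_rate(well)
        p, _ = fit_max_production_rate(well, gfit, "GFP")
        assert abs(p) < 1e-9 * 800.0

    def test_time_varying_production_matches_window_oracle(self):
        well = self._well(lambda t: 300.0 + 2.0 * t)
        gfit = fit_max_growth_rate(well)
        p, _ = fit_max_production_rate(well, gfit, "GFP")
        oracle = _oracle_production(well.times, gfit, well.channels["GFP"])
        assert p == pytest.approx(oracle, rel=0.05)

    def test_missing_channel_rejected(self):
        well = self._well(lambda t: np.full_like(t, 500.0))
        gfit = fit_max_growth_rate(well)
        with pytest.raises(KeyError):
            fit_max_production_rate(well, gfit, "RFP")


class TestPlateRecovery:
    def test_parameter_recovery_on_default_plate(self, default_plate):
        """Median growth-rate error < 2% and production-rate error < 5% on a
        default-noise synthetic plate."""
        plate, truth = default_plate
        fits = fit_plate(plate)
        m = fits.merge(truth, on=["well", "strain"])
        assert (m["status"] == "ok").all()
        rel_r = np.abs(m.r_max - m.true_r) / m.true_r
        rel_p = np.abs(m.p_max_GFP - m.true_p) / m.true_p
        assert np.median(rel_r) < 0.02
        assert np.median(rel_p) < 0.05
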