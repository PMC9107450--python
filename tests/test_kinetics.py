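"""RT-QuIC scoring: threshold, crossing, PAR/MaxFL, aggregation, CV%."""

import math

import numpy as np
import pandas as pd
import pytest

from synseed import kinetics, simulate
from synseed.kinetics import (PlateRun, aggregate_sample, analyze_well,
                              compute_threshold, cv_percent, load_plate)
from synseed.simulate import CurveSimSpec, logistic_crossing_time

TIMES = np.arange(120) * 0.5


def _plate_from(series_by_well: dict) -> PlateRun:
    layout = pd.DataFrame({
        "well": list(series_by_well),
        "sample_id": [f"S{i}" for i in range(len(series_by_well))],
        "group": "g", "replicate": 1,
    }).set_index("well")
    return PlateRun(times=TIMES, wells=dict(series_by_well), layout=layout)


class TestLoadPlate:
    def test_round_trip_through_csv(self, tmp_path, seeded_plate):
        plate, _ = seeded_plate
        simulate.write_plate_csv(plate, tmp_path / "p.csv", tmp_path / "l.csv")
        loaded = load_plate(tmp_path / "p.csv", tmp_path / "l.csv")
        assert loaded.n_wells == plate.n_wells
        assert loaded.times.size == 120
        for w in plate.wells:
            np.testing.assert_allclose(loaded.wells[w], plate.wells[w])

    def test_missing_layout_row_names_the_well(self, tmp_path, seeded_plate):
        plate, _ = seeded_plate
        simulate.write_plate_csv(plate, tmp_path / "p.csv", tmp_path / "l.csv")
        layout = pd.read_csv(tmp_path / "l.csv")
        dropped = layout["well"].iloc[0]
        layout.iloc[1:].to_csv(tmp_path / "l.csv", index=False)
        with pytest.raises(ValueError, match=dropped):
            load_plate(tmp_path / "p.csv", tmp_path / "l.csv")

    def test_duplicated_time_column_rejected(self, tmp_path, seeded_plate):
        plate, _ = seeded_plate
        simulate.write_plate_csv(plate, tmp_path / "p.csv", tmp_path / "l.csv")
        df = pd.read_csv(tmp_path / "p.csv")
        df["t_0.5 "] = df["t_0.5"]  # same stamp after strip -> still unique name
        df = df.rename(columns={"t_0.5 ": "t_0.5"})  # now truly duplicated
        df.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError):
            load_plate(tmp_path / "p.csv", tmp_path / "l.csv")

    def test_non_numeric_cell_names_well_and_column(self, tmp_path, seeded_plate):
        plate, _ = seeded_plate
        simulate.write_plate_csv(plate, tmp_path / "p.csv", tmp_path / "l.csv")
        df = pd.read_csv(tmp_path / "p.csv")
        df["t_3"] = df["t_3"].astype(object)
        df.loc[0, "t_3"] = "oops"
        df.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="t_3"):
            load_plate(tmp_path / "p.csv", tmp_path / "l.csv")


class TestThreshold:
    def test_zero_variance_pool(self):
        flat = np.full(120, 100.0)
        plate = _plate_from({"A1": flat, "A2": flat})
        assert compute_threshold(plate) == 100.0

    def test_known_pool_mean_and_sd(self):
        # Pooled baseline readings alternate 98/102: mean 100, sample SD
        # slightly above 2; with k_sd=25 the threshold is mean + 25*SD.
        base = np.tile([98.0, 102.0], 5)
        s1 = np.concatenate([base, np.full(110, 100.0)])
        plate = _plate_from({"A1": s1, "A2": s1})
        pool = np.tile([98.0, 102.0], 10)
        expected = pool.mean() + 25 * pool.std(ddof=1)
        assert compute_threshold(plate) == pytest.approx(expected)
        assert expected == pytest.approx(100 + 25 * pool.std(ddof=1))

    def test_k_sd_zero_gives_pool_mean(self):
        rng = np.random.default_rng(0)
        wells = {f"W{i}": rng.uniform(90, 110, 120) for i in range(4)}
        plate = _plate_from(wells)
        pool = np.concatenate([s[:10] for s in wells.values()])
        assert compute_threshold(plate, k_sd=0) == pytest.approx(pool.mean())


class TestAnalyzeWell:
    def test_midpoint_crossing_on_grid(self):
        spec = CurveSimSpec(baseline=0, amplitude=2000, rate_k=1,
                            midpoint_t50=20, noise_sd=0)
        _, f = simulate.simulate_curve(spec)
        wk = analyze_well(f, TIMES, threshold=1000.0)
        assert wk.t_cross == 20.0
        assert wk.par == pytest.approx(0.05)
        assert wk.positive

    def test_flat_series_negative(self):
        f = np.full(120, 50.0)
        wk = analyze_well(f, TIMES, threshold=1000.0)
        assert not wk.positive
        assert wk.t_cross is None and wk.par == 0.0
        assert wk.maxfl == 50.0

    def test_maxfl_is_tail_mean(self):
        f = np.zeros(120)
        f[-10:] = np.arange(1, 11)
        wk = analyze_well(f, TIMES, threshold=1e9)
        assert wk.maxfl == pytest.approx(5.5)

    def test_above_threshold_at_first_cycle_flagged(self):
        f = np.full(120, 5000.0)
        with pytest.warns(UserWarning, match="invalid-baseline"):
            wk = analyze_well(f, TIMES, threshold=1000.0, well="B2")
        assert wk.invalid_baseline and not wk.positive

    def test_interpolated_crossing_brackets_grid_value(self):
        spec = CurveSimSpec(baseline=0, amplitude=2000, rate_k=0.7,
                            midpoint_t50=20.3, noise_sd=0)
        _, f = simulate.simulate_curve(spec)
        on_grid = analyze_well(f, TIMES, threshold=1000.0)
        interp = analyze_well(f, TIMES, threshold=1000.0, interpolate=True)
        assert on_grid.t_cross - 0.5 < interp.t_cross <= on_grid.t_cross

    def test_noiseless_crossing_matches_analytic_oracle(self):
        # The detector must land on the first grid point at/after the exact
        # logistic crossing time, for arbitrary parameter draws.
        rng = np.random.default_rng(123)
        for _ in range(100):
            spec = CurveSimSpec(
                baseline=rng.uniform(5000, 15000),
                amplitude=rng.uniform(50_000, 200_000),
                rate_k=rng.uniform(0.3, 1.2),
                midpoint_t50=rng.uniform(10, 45),
                noise_sd=0,
            )
            threshold = spec.baseline + rng.uniform(0.1, 0.7) * spec.amplitude
            t_star = logistic_crossing_time(spec, threshold)
            _, f = simulate.simulate_curve(spec)
            wk = analyze_well(f, TIMES, threshold)
            expected = math.ceil(t_star / 0.5 - 1e-9) * 0.5
            if expected > TIMES[-1]:
                assert not wk.positive
            else:
                assert wk.t_cross == pytest.approx(expected)


class TestAggregateSample:
    def _wk(self, par, positive, maxfl=100.0, invalid=False):
        t_cross = 1.0 / par if par > 0 else None
        return kinetics.WellKinetics("w", 0.0, t_cross, par, maxfl, positive,
                                     invalid_baseline=invalid)

    def test_replicate_means_and_majority_positive(self):
        wells = [self._wk(0.05, True), self._wk(0.04, True), self._wk(0.0, False)]
        res = aggregate_sample(wells, "S1")
        assert res.par_mean == pytest.approx(0.03)
        assert res.n_positive_replicates == 2
        assert res.positive

    def test_all_flat_negative(self):
        wells = [self._wk(0.0, False)] * 3
        res = aggregate_sample(wells)
        assert res.par_mean == 0.0 and not res.positive

    def test_one_of_three_positive_is_negative_sample(self):
        wells = [self._wk(0.05, True), self._wk(0.0, False), self._wk(0.0, False)]
        assert not aggregate_sample(wells).positive

    def test_tie_at_half_counts_positive(self):
        wells = [self._wk(0.05, True), self._wk(0.0, False)]
        assert aggregate_sample(wells).positive

    def test_all_invalid_baseline_unevaluable(self):
        wells = [self._wk(0.0, False, invalid=True)] * 3
        res = aggregate_sample(wells)
        assert res.unevaluable and not res.positive

    def test_exclude_mode_averages_positive_wells_only(self):
        wells = [self._wk(0.05, True), self._wk(0.0, False)]
        res = aggregate_sample(wells, negative_par="exclude")
        assert res.par_mean == pytest.approx(0.05)


class TestCV:
    def test_two_point_cv(self):
        cv = cv_percent([90.0, 110.0])
        assert cv.cv_percent == pytest.approx(100 * abs(110 - 90) / np.sqrt(2) / 100)

    def test_constant_values_zero_cv(self):
        assert cv_percent([7.0, 7.0, 7.0]).cv_percent == 0.0

    def test_zero_mean_reported_absent(self):
        with pytest.warns(UserWarning, match="zero mean"):
            cv = cv_percent([-1.0, 1.0])
        assert cv.cv_percent is None

    def test_negative_controls_noisier_than_positives(self, seeded_plate):
        # MaxFL of flat negatives hovers near baseline noise, so their
        # relative spread exceeds that of strongly seeded wells.
        plate, _ = seeded_plate
        well_df, _ = kinetics.score_plate(plate)
        neg = well_df[well_df["group"] == "control/APOE4-"]
        pos = well_df[well_df["group"] == "AD+LB/APOE4-"]
        neg_shift = neg["MaxFL_AU"] - neg["MaxFL_AU"].min() + 1.0
        cv_neg = cv_percent(neg_shift, statistic="MaxFL").cv_percent
        cv_pos = cv_percent(pos["MaxFL_AU"], statistic="MaxFL").cv_percent
        assert cv_neg > cv_pos


class TestInvariantsAndEndToEnd:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        spec = CurveSimSpec(baseline=10_000, amplitude=120_000, rate_k=0.8,
                            midpoint_t50=22, noise_sd=300, rng_seed=8)
        _, f = simulate.simulate_curve(spec)
        thr = 25_000.0
        base = analyze_well(f, TIMES, thr)
        for c in rng.uniform(0.1, 10, size=5):
            scaled = analyze_well(c * f, TIMES, c * thr)
            assert scaled.t_cross == base.t_cross
            assert scaled.par == base.par
            assert scaled.positive == base.positive
            assert scaled.maxfl == pytest.approx(c * base.maxfl)

    def test_threshold_scales_with_readings(self, seeded_plate):
        plate, _ = seeded_plate
        thr = kinetics.compute_threshold(plate)
        scaled = kinetics.PlateRun(
            times=plate.times,
            wells={w: 3.0 * s for w, s in plate.wells.items()},
            layout=plate.layout)
        assert kinetics.compute_threshold(scaled) == pytest.approx(3.0 * thr)

    def test_earlier_t50_never_decreases_par(self):
        pars = []
        for t50 in (30.0, 25.0, 20.0, 15.0):
            spec = CurveSimSpec(baseline=0, amplitude=2000, rate_k=1,
                                midpoint_t50=t50, noise_sd=0)
            _, f = simulate.simulate_curve(spec)
            pars.append(analyze_well(f, TIMES, 1000.0).par)
        assert all(b >= a for a, b in zip(pars, pars[1:]))

    def test_group_means_mirror_disease_ordering(self):
        presets = [simulate.DEFAULT_PRESETS[k] for k in
                   ("AD/APOE4-", "AD+LB/APOE4-", "AD+LB/APOE4+")]
        plate, _ = simulate.simulate_plate(presets, samples_per_group=5,
                                           rng_seed=17)
        _, samples = kinetics.score_plate(plate)
        m = samples.groupby("group")[["PAR_mean_per_h", "MaxFL_mean_AU"]].mean()
        assert m.loc["AD+LB/APOE4-", "PAR_mean_per_h"] > \
            m.loc["AD/APOE4-", "PAR_mean_per_h"]
        assert m.loc["AD+LB/APOE4+", "MaxFL_mean_AU"] > \
            m.loc["AD+LB/APOE4-", "MaxFL_mean_AU"]
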