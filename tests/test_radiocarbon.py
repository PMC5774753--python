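"""Calibration, back-calibration, ordered Gibbs sampling, and age models."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from chronopewma.errors import (
    CurveParseError,
    DomainError,
    IncompatibleDateError,
    InfeasibleOrderingError,
    InsufficientDataError,
)
from chronopewma.radiocarbon import (
    CalibratedDensity,
    CalibrationCurve,
    RadiocarbonDate,
    apply_age_model,
    back_calibrate,
    build_age_model,
    calibrate,
    read_calibration_curve,
    sample_ordered_calendar_ages,
    synthesize_curve,
    write_calibration_curve,
)


class TestCurveIO:
    def test_reads_comments_and_comma_records(self, tmp_path):
        p = tmp_path / "tiny.14c"
        p.write_text(
            "# a comment\n# another\n"
            "12000,10200,30\n12500,10600,35\n13000,11050,40\n"
        )
        curve = read_calibration_curve(p)
        assert len(curve) == 3
        np.testing.assert_array_equal(curve.cal_age_grid, [12000, 12500, 13000])
        np.testing.assert_array_equal(curve.c14_age, [10200, 10600, 11050])

    def test_descending_input_sorted_ascending(self, tmp_path):
        asc = tmp_path / "asc.14c"
        desc = tmp_path / "desc.14c"
        asc.write_text("12000,10200,30\n12500,10600,35\n13000,11050,40\n")
        desc.write_text("13000,11050,40\n12500,10600,35\n12000,10200,30\n")
        a, d = read_calibration_curve(asc), read_calibration_curve(desc)
        np.testing.assert_array_equal(a.cal_age_grid, d.cal_age_grid)
        np.testing.assert_array_equal(a.c14_age, d.c14_age)

    def test_whitespace_and_extra_columns_accepted(self, tmp_path):
        p = tmp_path / "ws.14c"
        p.write_text("12000 10200 30 123 4\n12500\t10600\t35\t99\t1\n")
        curve = read_calibration_curve(p)
        assert len(curve) == 2

    def test_write_read_round_trip_bit_exact(self, tmp_path, wiggle_curve):
        p = tmp_path / "rt.14c"
        write_calibration_curve(wiggle_curve, p, comment="round trip")
        back = read_calibration_curve(p)
        np.testing.assert_array_equal(back.cal_age_grid, wiggle_curve.cal_age_grid)
        np.testing.assert_array_equal(back.c14_age, wiggle_curve.c14_age)
        np.testing.assert_array_equal(back.curve_error, wiggle_curve.curve_error)

    def test_malformed_field_names_line_number(self, tmp_path):
        p = tmp_path / "bad.14c"
        p.write_text("# header\n12000,10200,30\n12500,oops,35\n")
        with pytest.raises(CurveParseError) as err:
            read_calibration_curve(p)
        assert err.value.line_number == 3

    def test_too_few_records(self, tmp_path):
        p = tmp_path / "short.14c"
        p.write_text("# only one\n12000,10200,30\n")
        with pytest.raises(InsufficientDataError):
            read_calibration_curve(p)


class TestSynthesizeCurve:
    def test_degenerate_parameters_give_identity(self):
        curve = synthesize_curve((12000, 13000), step=5.0)
        np.testing.assert_allclose(curve.c14_age, curve.cal_age_grid)
        assert np.all(curve.curve_error == 0)

    def test_grid_point_count(self):
        curve = synthesize_curve((12000, 13000), step=5.0)
        assert len(curve) == 201

    def test_steep_wiggle_is_noninvertible(self):
        curve = synthesize_curve(
            (12000, 13000), wiggle_amplitude=200.0, wiggle_period=500.0, step=1.0
        )
        # scan: some radiocarbon age attained at well-separated calendar ages
        c14 = curve.c14_age
        assert np.any(np.diff(c14) < 0), "reversals should be present"
        target = c14[len(c14) // 2]
        crossings = np.where(np.diff(np.sign(c14 - target)) != 0)[0]
        assert len(crossings) > 1

    def test_zero_period_with_amplitude_rejected(self):
        with pytest.raises(ValueError):
            synthesize_curve((12000, 13000), wiggle_amplitude=10.0, wiggle_period=0.0)

    def test_curve_requires_two_points(self):
        with pytest.raises(InsufficientDataError):
            CalibrationCurve(np.array([12000.0]), np.array([10000.0]), np.array([30.0]))


class TestBackCalibrate:
    def test_identity_curve(self, identity_curve):
        assert back_calibrate(identity_curve, 12500.0) == pytest.approx(12500.0)

    def test_hand_linear_interpolation(self):
        curve = CalibrationCurve(
            np.array([12000.0, 12010.0]), np.array([10200.0, 10220.0]), np.zeros(2)
        )
        assert back_calibrate(curve, 12005.0) == pytest.approx(10210.0)

    def test_no_extrapolation(self, identity_curve):
        with pytest.raises(DomainError):
            back_calibrate(identity_curve, 11999.0)


class TestCalibrate:
    def test_gaussian_case_mode_and_sd(self, identity_curve):
        dens = calibrate(identity_curve, RadiocarbonDate(12500.0, 50.0), grid_step=1.0)
        assert dens.mode == pytest.approx(12500.0, abs=1.0)
        assert dens.sd == pytest.approx(50.0, abs=1.0)
        assert dens.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normalization_for_random_dates_on_wiggle_curve(self, wiggle_curve, rng):
        lo, hi = wiggle_curve.span
        for _ in range(25):
            theta = rng.uniform(lo + 50, hi - 50)
            date = RadiocarbonDate(back_calibrate(wiggle_curve, theta), 50.0)
            dens = calibrate(wiggle_curve, date, grid_step=1.0)
            assert abs(dens.mass.sum() - 1.0) < 1e-9

    def test_multimodal_density_matches_brute_force(self, wiggle_curve):
        # a radiocarbon age on a reversal: >= 2 well-separated calendar modes
        date = RadiocarbonDate(back_calibrate(wiggle_curve, 12750.0), 20.0)
        dens = calibrate(wiggle_curve, date, grid_step=1.0)

        # brute-force unnormalized density on the same grid
        grid = dens.cal_age_grid
        mu = np.interp(grid, wiggle_curve.cal_age_grid, wiggle_curve.c14_age)
        sig = np.interp(grid, wiggle_curve.cal_age_grid, wiggle_curve.curve_error)
        var = date.lab_error**2 + sig**2
        brute = np.exp(-0.5 * (date.c14_age - mu) ** 2 / var) / np.sqrt(var)
        brute /= brute.sum()
        np.testing.assert_allclose(dens.mass, brute, atol=1e-12)

        from scipy.signal import find_peaks

        peaks, _ = find_peaks(dens.mass, prominence=0.1 * dens.mass.max())
        brute_peaks, _ = find_peaks(brute, prominence=0.1 * brute.max())
        assert len(peaks) >= 2
        np.testing.assert_array_equal(peaks, brute_peaks)

    def test_incompatible_date_rejected(self, identity_curve):
        with pytest.raises(IncompatibleDateError):
            calibrate(identity_curve, RadiocarbonDate(50000.0, 10.0))

    def test_identity_round_trip_concentrates_on_truth(self, identity_curve):
        # zero curve error, tiny lab error: density mass within one cell of θ*
        theta = 12345.0
        date = RadiocarbonDate(back_calibrate(identity_curve, theta), 1.0)
        dens = calibrate(identity_curve, date, grid_step=1.0)
        near = np.abs(dens.cal_age_grid - theta) <= 2.0
        assert dens.mass[near].sum() > 0.95


class TestOrderedGibbs:
    def test_single_density_mean_matches(self, identity_curve):
        dens = calibrate(identity_curve, RadiocarbonDate(12500.0, 50.0))
        draws = sample_ordered_calendar_ages([dens], n_draws=10_000, seed=7)
        mc_se = dens.sd / np.sqrt(10_000)
        # Gibbs sweeps of a single date are i.i.d. draws; allow extra slack for
        # the piecewise-constant inversion
        assert abs(draws.mean() - dens.mean) < 3 * mc_se + 0.5

    def test_disjoint_in_order_supports_match_unconstrained(self, identity_curve):
        d1 = calibrate(identity_curve, RadiocarbonDate(12200.0, 20.0))
        d2 = calibrate(identity_curve, RadiocarbonDate(12800.0, 20.0))
        draws = sample_ordered_calendar_ages([d1, d2], n_draws=4000, seed=3)

        # unconstrained inverse-CDF oracle
        rng = np.random.default_rng(99)
        for j, dens in enumerate((d1, d2)):
            cdf = np.concatenate([[0.0], np.cumsum(dens.mass)])
            edges = np.concatenate(
                [dens.cal_age_grid - 0.5, [dens.cal_age_grid[-1] + 0.5]]
            )
            free = np.interp(rng.random(4000), cdf / cdf[-1], edges)
            stat = ks_2samp(draws[:, j], free)
            n, m = 4000, 4000
            crit_001 = 1.95 * np.sqrt((n + m) / (n * m))  # alpha = 0.01
            assert stat.statistic < crit_001

    def test_all_draws_strictly_ordered(self, experiment_curve):
        ages = np.linspace(12000, 13000, 5)
        dens = [
            calibrate(experiment_curve, RadiocarbonDate(back_calibrate(experiment_curve, a), 50.0))
            for a in ages
        ]
        draws = sample_ordered_calendar_ages(dens, n_draws=500, seed=5)
        assert np.all(np.diff(draws, axis=1) > 0)

    def test_reproducible_given_seed(self, experiment_curve):
        ages = np.linspace(12100, 12900, 3)
        dens = [
            calibrate(experiment_curve, RadiocarbonDate(back_calibrate(experiment_curve, a), 50.0))
            for a in ages
        ]
        a = sample_ordered_calendar_ages(dens, 50, seed=11)
        b = sample_ordered_calendar_ages(dens, 50, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_infeasible_ordering_detected(self):
        # two sharply dated horizons in inverted stratigraphic order
        grid1 = np.arange(12800.0, 12901.0)
        grid2 = np.arange(12000.0, 12101.0)
        m1 = np.exp(-0.5 * ((grid1 - 12850) / 10) ** 2)
        m2 = np.exp(-0.5 * ((grid2 - 12050) / 10) ** 2)
        older_first = CalibratedDensity(grid1, m1 / m1.sum())
        younger_second = CalibratedDensity(grid2, m2 / m2.sum())
        with pytest.raises(InfeasibleOrderingError):
            sample_ordered_calendar_ages([older_first, younger_second], 10, seed=0)


class TestAgeModel:
    def test_collinear_anchors_give_line(self):
        pos = np.arange(5.0)
        ages = 12000.0 + 250.0 * pos
        model = build_age_model(pos, ages)
        assert apply_age_model(model, [0.5])[0] == pytest.approx(12125.0)
        np.testing.assert_allclose(
            apply_age_model(model, [0.25, 0.75]), [12062.5, 12187.5]
        )

    def test_exact_at_anchors(self, rng):
        pos = np.sort(rng.uniform(0, 100, size=8))
        ages = np.sort(rng.uniform(12000, 13000, size=8))
        model = build_age_model(pos, ages)
        np.testing.assert_allclose(apply_age_model(model, pos), ages, rtol=0, atol=1e-9)

    def test_monotone_on_dense_grid(self, rng):
        for _ in range(20):
            k = rng.integers(3, 9)
            pos = np.sort(rng.uniform(0, 1000, size=k))
            while np.any(np.diff(pos) == 0):
                pos = np.sort(rng.uniform(0, 1000, size=k))
            ages = np.sort(rng.uniform(12000, 13000, size=k))
            model = build_age_model(pos, ages)
            dense = np.linspace(pos[0], pos[-1], 200)
            out = apply_age_model(model, dense)
            assert np.all(np.diff(out) >= 0)

    def test_no_extrapolation(self):
        model = build_age_model([0.0, 1.0], [12000.0, 13000.0])
        with pytest.raises(DomainError):
            apply_age_model(model, [1.5])

    def test_tied_positions_rejected(self):
        with pytest.raises(ValueError):
            build_age_model([0.0, 0.0, 1.0], [12000.0, 12100.0, 12200.0])

    def test_inverted_ages_rejected(self):
        with pytest.raises(ValueError):
            build_age_model([0.0, 1.0, 2.0], [12000.0, 12500.0, 12100.0])
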