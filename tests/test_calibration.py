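"""Calibration line, figures of merit and unit conversions."""

import numpy as np
import pytest

from lfaquant.calibration import (
    CalibrationModel,
    Reading,
    class_stats,
    concentration_from_quantity,
    fit_calibration,
    lod,
    loq,
    molarity_from_concentration,
    predict_quantity,
    quantity_from_concentration,
    r_squared,
    read_readings_csv,
    std_error,
    write_readings_csv,
)
from lfaquant.errors import DegenerateInputError

PAPER_LIKE_MODEL = CalibrationModel(slope=0.203, intercept=0.0118)


def _readings_on_line(slope, intercept, noise=None, n_per_class=3, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for x, q in enumerate((10.0, 100.0, 1000.0, 10000.0, 100000.0)):
        for i in range(n_per_class):
            y = slope * x + intercept
            if noise:
                y += rng.normal(0, noise)
            out.append(Reading(set_id=1, quantity_fg=q, tc_ratio=max(y, 0.0), reading_index=i))
    return out


class TestFitCalibration:
    def test_exact_line_recovered(self):
        model, diag = fit_calibration(_readings_on_line(0.2, 0.01))
        assert model.slope == pytest.approx(0.2, abs=1e-12)
        assert model.intercept == pytest.approx(0.01, abs=1e-12)
        assert model.sigma == pytest.approx(0.0, abs=1e-12)
        assert model.r2 == pytest.approx(1.0)

    def test_two_point_line(self):
        readings = [
            Reading(set_id=1, quantity_fg=10.0, tc_ratio=0.0),
            Reading(set_id=1, quantity_fg=100000.0, tc_ratio=0.8),
        ]
        model, _ = fit_calibration(readings)
        assert model.slope == pytest.approx(0.2)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_fixture_fit_matches_closed_form_oracle(self, fixture_readings):
        """Cross-check polyfit against the explicit least-squares formulas."""
        x = np.array([np.log10(r.quantity_fg / 10.0) for r in fixture_readings])
        y = np.array([r.tc_ratio for r in fixture_readings])
        sxx = ((x - x.mean()) ** 2).sum()
        slope_oracle = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept_oracle = y.mean() - slope_oracle * x.mean()
        model, _ = fit_calibration(fixture_readings)
        assert model.slope == pytest.approx(slope_oracle, abs=1e-10)
        assert model.intercept == pytest.approx(intercept_oracle, abs=1e-10)
        # recomputed values from the 3-decimal tables
        assert model.slope == pytest.approx(0.2002, abs=5e-4)
        assert model.intercept == pytest.approx(0.0146, abs=5e-4)
        assert model.r2 == pytest.approx(0.978, abs=2e-3)

    def test_single_quantity_rank_deficient(self):
        readings = [Reading(set_id=1, quantity_fg=100.0, tc_ratio=v) for v in (0.1, 0.2)]
        with pytest.raises(DegenerateInputError):
            fit_calibration(readings)

    @pytest.mark.parametrize("noise_sd", [0.001, 0.02])
    def test_parameter_recovery_from_noisy_synthetic_readings(self, noise_sd):
        """Fitted (m, b) approach the generating (0.2, 0.01) as noise shrinks."""
        readings = _readings_on_line(0.2, 0.01, noise=noise_sd, n_per_class=15, seed=42)
        model, _ = fit_calibration(readings)
        n = len(readings)
        x = np.array([np.log10(r.quantity_fg / 10.0) for r in readings])
        se_slope = 3 * noise_sd / np.sqrt(((x - x.mean()) ** 2).sum())
        se_intercept = 3 * noise_sd * np.sqrt(1 / n + x.mean() ** 2 / ((x - x.mean()) ** 2).sum())
        assert abs(model.slope - 0.2) < se_slope
        assert abs(model.intercept - 0.01) < se_intercept


class TestFiguresOfMerit:
    def test_r_squared_bounds_and_trivial_cases(self):
        model, diag = fit_calibration(_readings_on_line(0.2, 0.01, noise=0.05, seed=1))
        assert 0.0 <= r_squared(diag) <= 1.0
        assert diag.ss_residual <= diag.ss_total

    def test_std_error_hand_arithmetic(self):
        assert std_error([0, 0, 0], 3) == 0.0
        assert std_error([2], 1) == 2.0
        assert std_error([3, 4], 2) == pytest.approx(np.sqrt(25 / 2), abs=1e-4)  # 3.5355

    def test_std_error_rejects_empty(self):
        with pytest.raises(ValueError):
            std_error([], 0)

    def test_lod_loq_published_arithmetic(self):
        # sigma and slope as printed for the study's calibration
        assert lod(0.0, 0.007, 0.203) == pytest.approx(0.05672, abs=5e-5)
        assert loq(0.007, 0.203) == pytest.approx(0.34483, abs=5e-5)

    def test_lod_loq_degenerate_inputs(self):
        assert lod(0.5, 0.0, 0.2) == 0.5
        assert loq(0.0, 0.2) == 0.0
        with pytest.raises(ValueError):
            lod(0.0, 0.01, 0.0)
        with pytest.raises(ValueError):
            loq(0.01, 0.0)


class TestClassStats:
    def test_fixture_reproduces_published_stds(self, fixture_readings):
        stats = {s.quantity_fg: s for s in class_stats(fixture_readings)}
        assert stats[100.0].std == pytest.approx(0.021829, abs=5e-7)
        assert stats[10000.0].std == pytest.approx(0.055213, abs=5e-7)
        assert stats[100.0].n == 15

    def test_identical_readings_zero_spread(self):
        readings = [Reading(set_id=1, quantity_fg=q, tc_ratio=0.4)
                    for q in (100.0, 100.0, 100.0)]
        (s,) = class_stats(readings)
        assert s.std == pytest.approx(0.0, abs=1e-12)
        assert s.cv_percent == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_class_has_undefined_cv(self, fixture_readings):
        stats = {s.quantity_fg: s for s in class_stats(fixture_readings)}
        assert stats[10.0].mean == 0.0
        assert stats[10.0].cv_percent is None

    def test_singleton_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            class_stats([Reading(set_id=1, quantity_fg=100.0, tc_ratio=0.2)])

    def test_classes_ordered_by_descending_quantity(self, fixture_readings):
        quantities = [s.quantity_fg for s in class_stats(fixture_readings)]
        assert quantities == sorted(quantities, reverse=True)


class TestPredictQuantity:
    def test_intercept_maps_to_reference_quantity(self):
        assert predict_quantity(0.0118, PAPER_LIKE_MODEL) == pytest.approx(10.0)

    def test_top_class_from_calibrated_tc(self):
        assert predict_quantity(0.8238, PAPER_LIKE_MODEL) == pytest.approx(100000.0, rel=1e-9)

    def test_round_trips_noiseless_fit_values(self):
        model = CalibrationModel(slope=0.2, intercept=0.01)
        for q in (10.0, 1000.0, 100000.0):
            assert predict_quantity(model.predict_tc(q), model) == pytest.approx(q, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            predict_quantity(0.5, CalibrationModel(slope=0.0, intercept=0.1))


class TestUnits:
    def test_concentration_quantity_worked_examples(self):
        # 10 ng/mL in 10 uL -> 100 pg; 1 pg/mL in 10 uL -> 10 fg
        assert quantity_from_concentration(10_000.0, 10.0) == pytest.approx(100_000.0)
        assert quantity_from_concentration(1.0, 10.0) == pytest.approx(10.0)
        assert concentration_from_quantity(100_000.0, 10.0) == pytest.approx(10_000.0)
        assert concentration_from_quantity(0.0, 10.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            concentration_from_quantity(100.0, 0.0)

    def test_molarity_conversion(self):
        # 66,500 g/mol protein at 66.5 ng/mL is 1 nM
        assert molarity_from_concentration(66_500.0, 66_500.0) == pytest.approx(1.0)


def test_readings_csv_round_trip(tmp_path, fixture_readings):
    path = tmp_path / "readings.csv"
    write_readings_csv(fixture_readings, path)
    back = read_readings_csv(path)
    assert back == fixture_readings
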