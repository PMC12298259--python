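"""Conversion factors and the ESM/QAMS quantification equations."""

import math

import numpy as np
import pytest

from qams import (
    average_fx,
    content_percent,
    esm_conc_linear,
    esm_conc_log,
    fx_response_ratio,
    fx_slope_ratio,
    qams_conc_linear,
    qams_conc_log,
)
from qams.exceptions import ConfigurationError, DomainError
from qams.quantify import ConversionFactor, MarkerAssignment
from qams.reference import MARKER_ASSIGNMENT
from qams.validation import round2


class TestSlopeRatioFactors:
    @pytest.mark.parametrize(
        "detector, analyte, marker, expected_2dp",
        [
            ("PDA", "G-Rg1", "G-Rb1", 1.32),
            ("PDA", "G-Rd", "G-Rb1", 1.08),
            ("PDA", "M-R2", "G-Rb1", 0.04),
            ("ELSD", "G-Rg1", "G-Rb1", 0.95),
            ("ELSD", "M-R2", "G-Rb1", 0.92),
            ("ELSD", "V-R2", "G-Rb1", 0.97),
            ("ELSD", "V-R2", "M-R2", 1.05),
        ],
    )
    def test_reproduces_published_factors_from_calibration_slopes(
        self, noise_free_fits, detector, analyte, marker, expected_2dp
    ):
        f = fx_slope_ratio(noise_free_fits[(detector, analyte)], noise_free_fits[(detector, marker)])
        assert round2(f.value) == expected_2dp

    def test_marker_against_itself_is_exactly_one(self, noise_free_fits):
        fit = noise_free_fits[("PDA", "G-Rb1")]
        assert fx_slope_ratio(fit, fit).value == 1.0

    def test_reciprocal_factors_multiply_to_one(self, noise_free_fits):
        fx = fx_slope_ratio(noise_free_fits[("ELSD", "G-Rg1")], noise_free_fits[("ELSD", "G-Rb1")])
        inv = fx_slope_ratio(noise_free_fits[("ELSD", "G-Rb1")], noise_free_fits[("ELSD", "G-Rg1")])
        assert fx.value * inv.value == pytest.approx(1.0, rel=1e-12)

    def test_mixed_model_kinds_rejected(self, noise_free_fits):
        with pytest.raises(ConfigurationError):
            fx_slope_ratio(noise_free_fits[("PDA", "G-Rg1")], noise_free_fits[("ELSD", "G-Rb1")])


class TestResponseRatioFactors:
    @pytest.mark.parametrize(
        "analyte, marker, expected_2dp",
        [
            ("G-Rg1", "G-Rb1", 0.94),
            ("M-R2", "G-Rb1", 0.93),
            ("V-R2", "G-Rb1", 0.97),
            ("V-R2", "M-R2", 1.04),
        ],
    )
    def test_log_domain_mean_over_matched_levels_matches_published_values(
        self, noise_free_series, analyte, marker, expected_2dp
    ):
        f = fx_response_ratio(
            noise_free_series[("ELSD", analyte)], noise_free_series[("ELSD", marker)], "log"
        )
        assert round2(f.value) == expected_2dp

    def test_log_domain_agrees_with_closed_form_oracle(self, noise_free_series):
        # independent closed form: on a noise-free log-log line the per-level
        # ratio is (a_x + b_x/logC_x) / (a_s + b_s/logC_s)
        from qams.reference import C1_MG_PER_ML, ELSD_CALIBRATIONS

        ax, bx = ELSD_CALIBRATIONS["G-Rg1"]["slope"], ELSD_CALIBRATIONS["G-Rg1"]["intercept"]
        as_, bs = ELSD_CALIBRATIONS["G-Rb1"]["slope"], ELSD_CALIBRATIONS["G-Rb1"]["intercept"]
        cx = np.log10(C1_MG_PER_ML["G-Rg1"] * 1000 * 0.75 ** np.arange(6))
        cs = np.log10(C1_MG_PER_ML["G-Rb1"] * 1000 * 0.75 ** np.arange(6))
        expected = np.mean((ax + bx / cx) / (as_ + bs / cs))
        f = fx_response_ratio(
            noise_free_series[("ELSD", "G-Rg1")], noise_free_series[("ELSD", "G-Rb1")], "log"
        )
        assert f.value == pytest.approx(expected, rel=1e-12)

    def test_identical_series_give_unit_factor(self, noise_free_series):
        s = noise_free_series[("ELSD", "G-Rb1")]
        assert fx_response_ratio(s, s, "log").value == pytest.approx(1.0)
        assert fx_response_ratio(s, s, "linear").value == pytest.approx(1.0)

    def test_unequal_level_counts_rejected(self, noise_free_series):
        import dataclasses

        s = noise_free_series[("ELSD", "G-Rb1")]
        short = dataclasses.replace(
            s, conc_mg_per_ml=s.conc_mg_per_ml[:4], peak_area=s.peak_area[:4]
        )
        with pytest.raises(ConfigurationError):
            fx_response_ratio(noise_free_series[("ELSD", "G-Rg1")], short, "log")


class TestAverageFx:
    def test_symmetric_mean(self):
        fs = [
            ConversionFactor("x", "s", "PDA", "slope_ratio", v, provenance=f"intra_day({d})")
            for d, v in enumerate([1.30, 1.32, 1.34], 1)
        ]
        avg = average_fx(fs)
        assert avg.value == pytest.approx(1.32)
        assert avg.provenance.startswith("inter_day_mean")

    def test_single_element_is_itself(self):
        f = ConversionFactor("x", "s", "PDA", "slope_ratio", 1.1)
        assert average_fx([f]).value == pytest.approx(1.1)

    def test_mixed_identities_rejected(self):
        a = ConversionFactor("x", "s", "PDA", "slope_ratio", 1.1)
        b = ConversionFactor("y", "s", "PDA", "slope_ratio", 1.2)
        with pytest.raises(ConfigurationError):
            average_fx([a, b])


class TestLinearQuantification:
    def test_esm_inverts_the_published_line(self, noise_free_fits):
        fit = noise_free_fits[("PDA", "G-Rb1")]
        assert esm_conc_linear(52873.0, fit) == pytest.approx(0.2000, abs=1e-10)

    def test_area_equal_to_intercept_gives_zero(self, noise_free_fits):
        fit = noise_free_fits[("PDA", "G-Rb1")]
        assert esm_conc_linear(fit.intercept, fit) == pytest.approx(0.0, abs=1e-12)

    def test_area_below_intercept_gives_negative_concentration_unclamped(self, noise_free_fits):
        fit = noise_free_fits[("PDA", "G-Rb1")]
        conc = esm_conc_linear(fit.intercept - 1000, fit)
        assert conc < 0
        assert not fit.in_range(conc)

    def test_intercept_form_with_published_parameters_recovers_unit_concentration(
        self, noise_free_fits
    ):
        # analyte G-Rg1 measured at 1.0 mg/mL, marker G-Rb1 standard at 0.36 mg/mL
        fit_x = noise_free_fits[("PDA", "G-Rg1")]
        fit_s = noise_free_fits[("PDA", "G-Rb1")]
        f = fx_slope_ratio(fit_x, fit_s)
        conc = qams_conc_linear(
            859612.0, 54501.0, 0.36, f, intercept_x=fit_x.intercept, intercept_s=fit_s.intercept
        )
        assert conc == pytest.approx(1.0000, abs=1e-9)

    def test_intercept_free_form_reduces_to_esm_when_intercepts_vanish(self):
        from qams.calibration import CalibrationFit

        fit_x = CalibrationFit("linear", 120.0, 0.0, 1.0, 0.0, 0.0, 6, "mg/mL", (0.1, 1.0), "x", "PDA")
        fit_s = CalibrationFit("linear", 80.0, 0.0, 1.0, 0.0, 0.0, 6, "mg/mL", (0.1, 1.0), "s", "PDA")
        f = fx_slope_ratio(fit_x, fit_s)
        c_s = 0.5
        a_s = 80.0 * c_s
        a_x = 120.0 * 0.7
        assert qams_conc_linear(a_x, a_s, c_s, f) == pytest.approx(
            esm_conc_linear(a_x, fit_x), rel=1e-12
        )


class TestLogQuantification:
    def test_esm_inverts_the_published_elsd_line(self, noise_free_fits):
        fit = noise_free_fits[("ELSD", "G-Rb1")]
        area = 10 ** (1.4371 * math.log10(200.0) + 0.9450)
        assert esm_conc_log(area, fit) == pytest.approx(0.200, abs=1e-9)

    def test_area_ten_to_intercept_is_one_ug_per_ml(self, noise_free_fits):
        fit = noise_free_fits[("ELSD", "G-Rb1")]
        assert esm_conc_log(10 ** fit.intercept, fit) == pytest.approx(1e-3, rel=1e-9)

    def test_doubling_area_multiplies_concentration_by_power_law_factor(self, noise_free_fits):
        fit = noise_free_fits[("ELSD", "G-Rb1")]
        c1 = esm_conc_log(5000.0, fit)
        c2 = esm_conc_log(10000.0, fit)
        assert c2 / c1 == pytest.approx(2 ** (1 / fit.slope), rel=1e-12)

    def test_intercept_form_with_published_parameters_recovers_unit_concentration(
        self, noise_free_fits
    ):
        fit_x = noise_free_fits[("ELSD", "G-Rg1")]
        fit_s = noise_free_fits[("ELSD", "G-Rb1")]
        f = fx_slope_ratio(fit_x, fit_s)
        area_x = 10 ** (fit_x.slope * 3.0 + fit_x.intercept)  # 1.0 mg/mL = 1000 ug/mL
        area_s = 10 ** (fit_s.slope * math.log10(360.0) + fit_s.intercept)
        conc = qams_conc_log(
            area_x, area_s, 360.0, f, intercept_x=fit_x.intercept, intercept_s=fit_s.intercept
        )
        assert conc == pytest.approx(1.000, abs=1e-9)

    def test_nonpositive_area_rejected(self, noise_free_fits):
        with pytest.raises(DomainError):
            esm_conc_log(0.0, noise_free_fits[("ELSD", "G-Rb1")])


class TestIdentityTheorems:
    """Slope-factor QAMS equals ESM whenever the marker measurement lies on
    the marker's own calibration line — for every analyte/marker pair."""

    @pytest.mark.parametrize("detector", ["PDA", "ELSD"])
    def test_slope_factor_qams_equals_esm_for_every_pairing(self, noise_free_fits, detector):
        for analyte, marker in MARKER_ASSIGNMENT[detector].items():
            fit_x = noise_free_fits[(detector, analyte)]
            fit_s = noise_free_fits[(detector, marker)]
            f = fx_slope_ratio(fit_x, fit_s)
            c_s = fit_s.valid_range[1]
            a_s = fit_s.predict_area(c_s)
            c_true = 0.6 * fit_x.valid_range[1]
            a_x = fit_x.predict_area(c_true)
            if detector == "PDA":
                esm = esm_conc_linear(a_x, fit_x)
                qams = qams_conc_linear(
                    a_x, a_s, c_s, f, intercept_x=fit_x.intercept, intercept_s=fit_s.intercept
                )
            else:
                esm = esm_conc_log(a_x, fit_x)
                qams = qams_conc_log(
                    a_x, a_s, c_s * 1000, f,
                    intercept_x=fit_x.intercept, intercept_s=fit_s.intercept,
                )
            assert qams == pytest.approx(esm, rel=1e-12)
            assert esm == pytest.approx(c_true, rel=1e-9)

    def test_self_marker_quantification_reproduces_esm_for_all_four_equations(
        self, noise_free_fits, noise_free_series
    ):
        # quantifying the marker against itself means the analyte and marker
        # measurements are one and the same injection (A_x = A_s, C known);
        # all four single-marker equations must then return the ESM result
        for detector in ("PDA", "ELSD"):
            fit = noise_free_fits[(detector, "G-Rb1")]
            series = noise_free_series[(detector, "G-Rb1")]
            domain = "linear" if detector == "PDA" else "log"
            f_ratio = fx_response_ratio(series, series, domain)
            f_slope = fx_slope_ratio(fit, fit)
            c_s = fit.valid_range[1]
            a_s = fit.predict_area(c_s)
            a_x = a_s
            if detector == "PDA":
                esm = esm_conc_linear(a_x, fit)
                assert qams_conc_linear(a_x, a_s, c_s, f_ratio) == pytest.approx(esm, rel=1e-9)
                assert qams_conc_linear(
                    a_x, a_s, c_s, f_slope, intercept_x=fit.intercept, intercept_s=fit.intercept
                ) == pytest.approx(esm, rel=1e-12)
            else:
                esm = esm_conc_log(a_x, fit)
                assert qams_conc_log(a_x, a_s, c_s * 1000, f_ratio) == pytest.approx(
                    esm, rel=1e-9
                )
                assert qams_conc_log(
                    a_x, a_s, c_s * 1000, f_slope,
                    intercept_x=fit.intercept, intercept_s=fit.intercept,
                ) == pytest.approx(esm, rel=1e-12)
            assert esm == pytest.approx(c_s, rel=1e-9)


class TestUnitCoherence:
    def test_log_quantification_is_invariant_to_the_fitting_unit_convention(self):
        """Quantifying via the ug/mL convention (with the -3 back-shift) and
        via an equivalent mg/mL-domain formulation gives identical mg/mL."""
        a, b_ug = 1.4371, 0.9450
        b_mg = b_ug + 3 * a  # same power law expressed against mg/mL
        area = 10 ** (a * math.log10(0.2 * 1000) + b_ug)
        from qams.calibration import CalibrationFit

        fit_ug = CalibrationFit("loglog", a, b_ug, 1.0, 0.0, 0.0, 6, "ug/mL", (0.09, 0.36))
        c_ug_convention = esm_conc_log(area, fit_ug)
        c_mg_convention = 10 ** ((math.log10(area) - b_mg) / a)
        assert c_ug_convention == pytest.approx(c_mg_convention, rel=1e-12)
        assert c_ug_convention == pytest.approx(0.2, rel=1e-12)


class TestContent:
    def test_direct_formula(self):
        assert content_percent(1.0, 5.0, 100.0) == pytest.approx(5.00)
        assert content_percent(0.0, 5.0, 100.0) == 0.0
        assert content_percent(1.142, 5.0, 100.0) == pytest.approx(5.71)

    def test_nonpositive_volume_or_mass_rejected(self):
        with pytest.raises(DomainError):
            content_percent(1.0, 0.0, 100.0)
        with pytest.raises(DomainError):
            content_percent(1.0, 5.0, -1.0)


class TestMarkerAssignment:
    def test_published_assignment_is_valid_and_resolves(self):
        ma = MarkerAssignment(MARKER_ASSIGNMENT)
        assert ma.marker_for("PDA", "G-Rg1") == "G-Rb1"
        assert ma.marker_for("ELSD", "V-R2") == "M-R2"

    def test_marker_not_mapping_to_itself_rejected(self):
        with pytest.raises(ConfigurationError):
            MarkerAssignment({"PDA": {"x": "s", "s": "x"}})
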