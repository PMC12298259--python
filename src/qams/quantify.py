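"""Relative conversion factors and single-marker (QAMS) quantification.

The external-standards method (ESM) inverts each analyte's own calibration
curve.  QAMS instead quantifies every analyte from a single marker standard
``s`` through a relative conversion factor ``F_x`` relating the analyte's
detector response to the marker's.  Two constructions of ``F_x`` are
implemented per detector domain:

* response ratio — the mean over matched dilution levels of
  ``(A_x/C_x) / (A_s/C_s)`` (linear, PDA) or
  ``(log10 A_x / log10 C_x) / (log10 A_s / log10 C_s)`` (log, ELSD,
  concentrations in ug/mL);
* slope ratio — ``a_x / a_s`` from the fitted calibration slopes.

Quantification then needs only a fresh measurement of the marker
``(A_s, C_s)`` and, for the intercept-aware variants, the stored analyte and
marker intercepts.  With the slope-ratio factor and a marker measurement
lying on the marker's own calibration line, QAMS reproduces the ESM result
exactly — the identity the method's validation rests on.

Concentrations returned are always in mg/mL; dry-weight content follows as
``H(%) = V * C / m * 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .calibration import CalibrationFit, UG_PER_MG
from .exceptions import ConfigurationError, DomainError
from .simulate import CalibrationSeries

FxMethod = Literal["response_ratio", "slope_ratio"]


@dataclass(frozen=True)
class ConversionFactor:
    """Analyte-vs-marker response factor F_x (unitless)."""

    analyte: str
    marker: str
    detector: str
    method: FxMethod
    value: float
    provenance: str = "intra_day"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ConfigurationError(
                f"F_x must be positive, got {self.value} for {self.analyte}/{self.marker}"
            )


@dataclass(frozen=True)
class MarkerAssignment:
    """Per-detector mapping analyte -> single marker; markers map to themselves."""

    assignment: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        for detector, mapping in self.assignment.items():
            for analyte, marker in mapping.items():
                if marker not in mapping:
                    raise ConfigurationError(
                        f"marker {marker!r} for {analyte!r} on {detector} is not itself mapped"
                    )
                if mapping[marker] != marker:
                    raise ConfigurationError(
                        f"marker {marker!r} on {detector} must map to itself"
                    )

    def marker_for(self, detector: str, analyte: str) -> str:
        try:
            return self.assignment[detector][analyte]
        except KeyError:
            raise ConfigurationError(
                f"no marker assigned for {analyte!r} on detector {detector!r}"
            ) from None


@dataclass(frozen=True)
class QuantResult:
    """Concentration and dry-weight content of one analyte by one method."""

    analyte: str
    method: str  # ESM | QAMS_ratio | QAMS_slope
    detector: str
    conc_mg_per_ml: float
    content_pct: float
    marker: str | None = None
    in_range: bool = True


def fx_slope_ratio(fit_x: CalibrationFit, fit_s: CalibrationFit) -> ConversionFactor:
    """F_x = a_x / a_s from two calibration fits of the same kind/detector."""
    if fit_x.model_kind != fit_s.model_kind:
        raise ConfigurationError(
            f"cannot ratio slopes of a {fit_x.model_kind} and a {fit_s.model_kind} fit"
        )
    if fit_x.detector is not None and fit_s.detector is not None and fit_x.detector != fit_s.detector:
        raise ConfigurationError("slope-ratio factors require fits from the same detector")
    if fit_s.slope == 0:
        raise DomainError("marker slope is zero; F_x undefined")
    return ConversionFactor(
        analyte=fit_x.compound or "x",
        marker=fit_s.compound or "s",
        detector=fit_x.detector or fit_s.detector or "",
        method="slope_ratio",
        value=fit_x.slope / fit_s.slope,
        provenance=f"intra_day({fit_x.day})" if fit_x.day is not None else "intra_day",
    )


def fx_response_ratio(
    series_x: CalibrationSeries,
    series_s: CalibrationSeries,
    domain: Literal["linear", "log"],
) -> ConversionFactor:
    """Mean response-ratio factor over matched dilution levels.

    ``linear``: mean over levels i of (A_x,i/C_x,i)/(A_s,i/C_s,i), C in mg/mL.
    ``log``: mean of (log10 A_x,i / log10 C_x,i)/(log10 A_s,i / log10 C_s,i)
    with concentrations in ug/mL; every log10(C) must be nonzero.
    """
    if len(series_x.conc_mg_per_ml) != len(series_s.conc_mg_per_ml):
        raise ConfigurationError("analyte and marker series must have matched level counts")
    if domain == "linear":
        per_level = (series_x.peak_area / series_x.conc_mg_per_ml) / (
            series_s.peak_area / series_s.conc_mg_per_ml
        )
    else:
        cx = np.log10(series_x.conc_mg_per_ml * UG_PER_MG)
        cs = np.log10(series_s.conc_mg_per_ml * UG_PER_MG)
        if np.any(cx == 0) or np.any(cs == 0):
            raise DomainError("log10 concentration is zero at some level; Eq-8 ratio undefined")
        if np.any(series_x.peak_area <= 0) or np.any(series_s.peak_area <= 0):
            raise DomainError("nonpositive area in log-domain response ratio")
        per_level = (np.log10(series_x.peak_area) / cx) / (np.log10(series_s.peak_area) / cs)
    return ConversionFactor(
        analyte=series_x.compound,
        marker=series_s.compound,
        detector=series_x.detector,
        method="response_ratio",
        value=float(np.mean(per_level)),
        provenance=f"intra_day({series_x.day})",
    )


def average_fx(factors: Sequence[ConversionFactor]) -> ConversionFactor:
    """Arithmetic mean of per-day factors sharing analyte/marker/detector/method."""
    if not factors:
        raise ConfigurationError("cannot average an empty factor list")
    first = factors[0]
    for f in factors[1:]:
        if (f.analyte, f.marker, f.detector, f.method) != (
            first.analyte,
            first.marker,
            first.detector,
            first.method,
        ):
            raise ConfigurationError("cannot average factors with mixed identities")
    days = ",".join(f.provenance for f in factors)
    return ConversionFactor(
        analyte=first.analyte,
        marker=first.marker,
        detector=first.detector,
        method=first.method,
        value=float(np.mean([f.value for f in factors])),
        provenance=f"inter_day_mean({days})",
    )


def esm_conc_linear(area: float, fit: CalibrationFit) -> float:
    """External-standard concentration from a linear fit: C = (A - b)/a, mg/mL."""
    if fit.model_kind != "linear":
        raise ConfigurationError("esm_conc_linear needs a linear fit")
    if fit.slope == 0:
        raise DomainError("zero slope; concentration undefined")
    return (area - fit.intercept) / fit.slope


def qams_conc_linear(
    area_x: float,
    area_s: float,
    conc_s: float,
    factor: ConversionFactor,
    *,
    intercept_x: float | None = None,
    intercept_s: float | None = None,
) -> float:
    """Single-marker concentration in the linear (PDA) domain, mg/mL.

    Without intercepts: ``C_x = A_x * C_s / (F_x * A_s)``.  With stored
    intercepts: ``C_x = (A_x - b_x) * C_s / ((A_s - b_s) * F_x)``, which
    equals the ESM inversion whenever the marker measurement lies on its own
    calibration line and F_x is the slope ratio.
    """
    if conc_s <= 0:
        raise DomainError("marker concentration must be positive")
    if intercept_x is None or intercept_s is None:
        if area_s <= 0:
            raise DomainError("marker area must be positive for the intercept-free form")
        return area_x * conc_s / (factor.value * area_s)
    denom = (area_s - intercept_s) * factor.value
    if denom == 0:
        raise DomainError("marker area equals its intercept; QAMS denominator is zero")
    return (area_x - intercept_x) * conc_s / denom


def esm_conc_log(area: float, fit: CalibrationFit) -> float:
    """External-standard concentration from a log-log fit, mg/mL.

    ``C = 10**((log10 A - b)/a - 3)``; the -3 converts the ug/mL fitting
    convention back to mg/mL.
    """
    if fit.model_kind != "loglog":
        raise ConfigurationError("esm_conc_log needs a log-log fit")
    if area <= 0:
        raise DomainError(f"peak area must be positive, got {area}")
    return 10.0 ** ((math.log10(area) - fit.intercept) / fit.slope - 3.0)


def qams_conc_log(
    area_x: float,
    area_s: float,
    conc_s_ug_per_ml: float,
    factor: ConversionFactor,
    *,
    intercept_x: float | None = None,
    intercept_s: float | None = None,
) -> float:
    """Single-marker concentration in the log (ELSD) domain, mg/mL.

    Without intercepts:
    ``C_x = 10**(log10(A_x) * log10(C_s) / (F_x * log10(A_s)) - 3)``.
    With stored intercepts:
    ``C_x = 10**((log10(A_x) - b_x) * log10(C_s) / ((log10(A_s) - b_s) * F_x) - 3)``.
    ``C_s`` is the marker concentration in ug/mL.
    """
    if area_x <= 0 or area_s <= 0:
        raise DomainError("areas must be positive in the log domain")
    if conc_s_ug_per_ml <= 0:
        raise DomainError("marker concentration must be positive")
    log_cs = math.log10(conc_s_ug_per_ml)
    if log_cs == 0:
        raise DomainError("log10 of the marker concentration is zero; QAMS undefined")
    log_ax = math.log10(area_x)
    log_as = math.log10(area_s)
    if intercept_x is None or intercept_s is None:
        if log_as == 0:
            raise DomainError("log10 of the marker area is zero; QAMS denominator is zero")
        exponent = log_ax * log_cs / (factor.value * log_as)
    else:
        denom = (log_as - intercept_s) * factor.value
        if denom == 0:
            raise DomainError("marker log-area equals its intercept; QAMS denominator is zero")
        exponent = (log_ax - intercept_x) * log_cs / denom
    return 10.0 ** (exponent - 3.0)


def content_percent(conc_mg_per_ml: float, volume_ml: float, mass_mg: float) -> float:
    """Dry-weight content H(%) = V * C / m * 100."""
    if volume_ml <= 0 or mass_mg <= 0:
        raise DomainError("volume and mass must be positive")
    return volume_ml * conc_mg_per_ml / mass_mg * 100.0
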