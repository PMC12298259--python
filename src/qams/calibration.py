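"""Detector calibration: linear (PDA) and log-log (ELSD) response fits.

The photodiode-array detector responds linearly to concentration,

    area = a * C + b,          C in mg/mL,

while the evaporative light-scattering detector follows a power law that is
linear in double-logarithmic coordinates,

    log10(area) = a * log10(C) + b,    C in ug/mL.

Both are fitted by ordinary least squares.  The correlation coefficient R
(not R^2), the residual standard deviation and the standard error of the
slope are reported alongside the coefficients.  Detection and quantification
limits follow the ICH residual-SD formulation, LOD = 3.3*sigma/slope and
LOQ = 10*sigma/slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, FitError

ModelKind = Literal["linear", "loglog"]
ConcUnit = Literal["mg/mL", "ug/mL"]

#: mg/mL -> ug/mL
UG_PER_MG = 1000.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration standard injection.

    Concentration is always stored in mg/mL (the canonical unit); the
    log-log fitter converts to ug/mL internally.
    """

    concentration: float  # mg/mL
    peak_area: float
    level_index: int = 0
    day: int = 1
    replicate: int = 1


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a least-squares calibration fit.

    ``slope``/``intercept`` are in the coordinates of ``model_kind`` and
    ``conc_unit`` (area per mg/mL for linear fits; unitless slope and
    log10-area intercept, concentration in ug/mL, for log-log fits).
    ``valid_range`` is always in mg/mL.
    """

    model_kind: ModelKind
    slope: float
    intercept: float
    r: float
    residual_sd: float
    slope_se: float
    n_points: int
    conc_unit: ConcUnit
    valid_range: tuple[float, float]
    compound: str | None = None
    detector: str | None = None
    day: int | None = None

    def predict_area(self, conc_mg_per_ml: float | np.ndarray) -> float | np.ndarray:
        """Noise-free detector response at a concentration in mg/mL."""
        c = np.asarray(conc_mg_per_ml, dtype=float)
        if self.model_kind == "linear":
            out = self.slope * c + self.intercept
        else:
            out = 10.0 ** (self.slope * np.log10(c * UG_PER_MG) + self.intercept)
        return float(out) if np.isscalar(conc_mg_per_ml) else out

    def in_range(self, conc_mg_per_ml: float) -> bool:
        lo, hi = self.valid_range
        return lo <= conc_mg_per_ml <= hi


def _as_arrays(points: Sequence[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    conc = np.array([p.concentration for p in points], dtype=float)
    area = np.array([p.peak_area for p in points], dtype=float)
    return conc, area


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """OLS of y on x; returns slope, intercept, r, residual SD, slope SE."""
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    residual_sd = float(math.sqrt(float(resid @ resid) / dof))
    return float(res.slope), float(res.intercept), float(res.rvalue), residual_sd, float(res.stderr)


def fit_linear(
    points: Sequence[CalibrationPoint],
    *,
    compound: str | None = None,
    detector: str | None = None,
    day: int | None = None,
) -> CalibrationFit:
    """Fit ``area = a * C + b`` with C in mg/mL (PDA model).

    Requires at least three distinct concentrations.
    """
    conc, area = _as_arrays(points)
    if len(np.unique(conc)) < 3:
        raise FitError(
            f"linear calibration needs >=3 distinct concentrations, got {len(np.unique(conc))}"
        )
    slope, intercept, r, residual_sd, slope_se = _ols(conc, area)
    return CalibrationFit(
        model_kind="linear",
        slope=slope,
        intercept=intercept,
        r=r,
        residual_sd=residual_sd,
        slope_se=slope_se,
        n_points=len(points),
        conc_unit="mg/mL",
        valid_range=(float(conc.min()), float(conc.max())),
        compound=compound,
        detector=detector,
        day=day,
    )


def fit_loglog(
    points: Sequence[CalibrationPoint],
    *,
    compound: str | None = None,
    detector: str | None = None,
    day: int | None = None,
) -> CalibrationFit:
    """Fit ``log10(area) = a * log10(C_ug) + b`` (ELSD model).

    Concentrations are converted from the canonical mg/mL to ug/mL before
    taking logarithms; all areas must be strictly positive.
    """
    conc, area = _as_arrays(points)
    if len(np.unique(conc)) < 3:
        raise FitError(
            f"log-log calibration needs >=3 distinct concentrations, got {len(np.unique(conc))}"
        )
    bad = np.flatnonzero(area <= 0)
    if bad.size:
        i = int(bad[0])
        raise DomainError(
            f"nonpositive peak area {area[i]} at concentration {conc[i]} mg/mL "
            "cannot be log-transformed"
        )
    if np.any(conc <= 0):
        raise DomainError("nonpositive concentration in calibration series")
    x = np.log10(conc * UG_PER_MG)
    y = np.log10(area)
    slope, intercept, r, residual_sd, slope_se = _ols(x, y)
    return CalibrationFit(
        model_kind="loglog",
        slope=slope,
        intercept=intercept,
        r=r,
        residual_sd=residual_sd,
        slope_se=slope_se,
        n_points=len(points),
        conc_unit="ug/mL",
        valid_range=(float(conc.min()), float(conc.max())),
        compound=compound,
        detector=detector,
        day=day,
    )


def lod_loq(fit: CalibrationFit) -> tuple[float, float]:
    """Detection and quantification limits in mg/mL.

    Linear fits: LOD = 3.3*sigma/a, LOQ = 10*sigma/a, where sigma is the
    residual SD of the regression.  Log-log fits: the same ratios are formed
    in the log10 domain and back-transformed, i.e.
    ``LOD = 10**(3.3*sigma/a - 3)`` mg/mL (the -3 undoes the ug/mL
    convention).  Note the log-log limits tend to 1 ug/mL, not zero, as the
    residual SD vanishes.
    """
    if fit.slope == 0:
        raise DomainError("LOD/LOQ undefined for zero slope")
    lod_ratio = 3.3 * fit.residual_sd / fit.slope
    loq_ratio = 10.0 * fit.residual_sd / fit.slope
    if fit.model_kind == "linear":
        return lod_ratio, loq_ratio
    return 10.0 ** (lod_ratio - 3.0), 10.0 ** (loq_ratio - 3.0)
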