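"""Synthetic peak-area data with the statistical structure the analysis assumes.

No instrument data ship with the package: every downstream stage (calibration,
conversion factors, quantification, validation) is exercised on simulated
integrated peak areas.  The generator emulates

* six-level geometric dilution series (factor 0.75) of the standard stocks,
* a linear PDA response ``area = a*C + b`` with additive Gaussian area noise,
* a power-law ELSD response, linear in log10-log10 coordinates with
  concentration in ug/mL, with Gaussian noise on log10(area)
  (i.e. multiplicative on the area),
* day-to-day multiplicative response drift and an analogous per-laboratory
  bias, and
* three-level spike-recovery designs (80/100/120% of nominal content,
  three preparations each).

The unit of data is the integrated peak area; no retention times or peak
shapes are synthesised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .exceptions import ConfigurationError, DomainError

DetectorKind = Literal["PDA", "ELSD"]

PEAK_TABLE_COLUMNS = [
    "sample_id",
    "compound",
    "detector",
    "day",
    "lab",
    "replicate",
    "known_conc_mg_per_ml",
    "peak_area",
    "role",
]


@dataclass(frozen=True)
class DetectorModel:
    """Generating response model of one compound on one detector.

    For PDA, ``slope`` is area per (mg/mL), ``intercept`` is in area units
    and ``noise_sd`` is an additive area SD.  For ELSD, ``slope`` is the
    unitless log-log exponent, ``intercept`` is in log10-area units with
    concentration in ug/mL, and ``noise_sd`` is the SD of Gaussian noise on
    log10(area).
    """

    detector_kind: DetectorKind
    slope: float
    intercept: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError(f"response slope must be positive, got {self.slope}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")

    def response(self, conc_mg_per_ml: np.ndarray | float) -> np.ndarray | float:
        """Noise-free peak area at a concentration in mg/mL."""
        c = np.asarray(conc_mg_per_ml, dtype=float)
        if np.any(c <= 0):
            raise DomainError("concentration must be positive")
        if self.detector_kind == "PDA":
            out = self.slope * c + self.intercept
        else:
            out = 10.0 ** (self.slope * np.log10(c * 1000.0) + self.intercept)
        return float(out) if np.isscalar(conc_mg_per_ml) else out


@dataclass(frozen=True)
class DilutionDesign:
    """Geometric dilution of per-compound stock solutions."""

    c1_by_compound: Mapping[str, float]
    dilution_factor: float = reference.DILUTION_FACTOR
    n_levels: int = reference.N_LEVELS

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution_factor <= 1.0):
            raise ConfigurationError(
                f"dilution factor must be in (0, 1], got {self.dilution_factor}"
            )
        if self.n_levels < 2:
            raise ConfigurationError(f"need at least 2 levels, got {self.n_levels}")
        for compound, c1 in self.c1_by_compound.items():
            if c1 <= 0:
                raise ConfigurationError(f"stock concentration for {compound} must be positive")


@dataclass(frozen=True)
class CalibrationSeries:
    """Ordered concentration/area points of one compound on one detector/day."""

    compound: str
    detector: DetectorKind
    conc_mg_per_ml: np.ndarray
    peak_area: np.ndarray
    day: int = 1
    lab: str = "lab1"


@dataclass(frozen=True)
class Scenario:
    """True state of a simulated quantification study.

    ``true_contents`` are dry-weight percentages per compound; the solution
    concentration follows from the preparation constants as
    ``C = H * m / (100 * V)``.  ``day_drift`` and ``lab_bias`` are
    multiplicative response factors applied on top of the noise-free
    response (default 1.0).  ``seed`` fully determines every random draw.
    """

    true_contents: Mapping[str, float]
    sample_mass_mg: float = reference.SAMPLE_MASS_MG
    volume_ml: float = reference.SAMPLE_VOLUME_ML
    day_drift: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    lab_bias: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    spike_levels: tuple[float, ...] = (0.8, 1.0, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_mass_mg <= 0 or self.volume_ml <= 0:
            raise ConfigurationError("sample mass and volume must be positive")
        for day, factors in self.day_drift.items():
            for compound, f in factors.items():
                if f <= 0:
                    raise ConfigurationError(
                        f"drift factor for day {day}/{compound} must be positive"
                    )

    def true_concentration(self, compound: str) -> float:
        """Invert H = V*C/m*100 to the true solution concentration (mg/mL)."""
        try:
            h = self.true_contents[compound]
        except KeyError:
            raise ConfigurationError(f"no true content for compound {compound!r}") from None
        return h * self.sample_mass_mg / (100.0 * self.volume_ml)

    def drift_factor(self, day: int, lab: str, compound: str) -> float:
        f = self.day_drift.get(day, {}).get(compound, 1.0)
        f *= self.lab_bias.get(lab, {}).get(compound, 1.0)
        return f


def make_dilution_series(design: DilutionDesign, compound: str) -> np.ndarray:
    """Concentrations C1..Cn (mg/mL), descending: ``C_i = C1 * factor**(i-1)``."""
    if compound not in design.c1_by_compound:
        raise ConfigurationError(f"compound {compound!r} not in dilution design")
    c1 = design.c1_by_compound[compound]
    return c1 * design.dilution_factor ** np.arange(design.n_levels)


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_calibration(
    concentrations: Sequence[float] | np.ndarray,
    model: DetectorModel,
    seed: int | np.random.Generator,
    *,
    compound: str = "",
    day: int = 1,
    lab: str = "lab1",
    drift: float = 1.0,
) -> CalibrationSeries:
    """Simulate one calibration series at the given concentrations (mg/mL).

    PDA areas get additive Gaussian noise; ELSD noise is added to
    log10(area), so generated ELSD areas are strictly positive.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise DomainError("all calibration concentrations must be positive")
    rng = _rng(seed)
    eps = rng.normal(0.0, model.noise_sd, size=conc.shape) if model.noise_sd > 0 else 0.0
    if model.detector_kind == "PDA":
        area = drift * np.asarray(model.response(conc)) + eps
    else:
        log_area = model.slope * np.log10(conc * 1000.0) + model.intercept + eps
        area = drift * 10.0 ** log_area
    return CalibrationSeries(
        compound=compound,
        detector=model.detector_kind,
        conc_mg_per_ml=conc,
        peak_area=np.asarray(area, dtype=float),
        day=day,
        lab=lab,
    )


def _measure_area(
    model: DetectorModel, conc: float, drift: float, rng: np.random.Generator
) -> float:
    eps = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    if model.detector_kind == "PDA":
        return drift * float(model.response(conc)) + eps
    return drift * 10.0 ** (model.slope * math.log10(conc * 1000.0) + model.intercept + eps)


def simulate_sample_set(
    scenario: Scenario,
    models: Mapping[str, DetectorModel],
    n_replicates: int,
    *,
    day: int = 1,
    lab: str = "lab1",
    seed: int | np.random.Generator | None = None,
    sample_prefix: str = "sample",
) -> pd.DataFrame:
    """Simulate replicate sample-solution measurements on one day/lab.

    ``models`` maps compound -> DetectorModel for a single detector.  Each
    replicate is an independently prepared sample solution; the day/lab
    drift factor multiplies the noise-free response.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    records = []
    for compound, model in models.items():
        conc = scenario.true_concentration(compound)
        drift = scenario.drift_factor(day, lab, compound)
        for rep in range(1, n_replicates + 1):
            records.append(
                {
                    "sample_id": f"{sample_prefix}-d{day}-{lab}-r{rep}",
                    "compound": compound,
                    "detector": model.detector_kind,
                    "day": day,
                    "lab": lab,
                    "replicate": rep,
                    "known_conc_mg_per_ml": np.nan,
                    "peak_area": _measure_area(model, conc, drift, rng),
                    "role": "sample",
                }
            )
    return pd.DataFrame.from_records(records, columns=PEAK_TABLE_COLUMNS)


def make_spike_design(
    scenario: Scenario,
    models: Mapping[str, DetectorModel],
    *,
    n_preparations: int = 3,
    day: int = 1,
    lab: str = "lab1",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the three-level standard-addition (spike recovery) design.

    Standards are added at ``scenario.spike_levels`` (fractions of each
    compound's nominal content, default 80/100/120%), ``n_preparations``
    independent preparations per level — nine spiked records per compound by
    default.  The *added* concentration (mg/mL) is recorded in
    ``known_conc_mg_per_ml``; the measured area reflects base + added.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    records = []
    for compound, model in models.items():
        base_conc = scenario.true_concentration(compound)
        drift = scenario.drift_factor(day, lab, compound)
        for li, level in enumerate(scenario.spike_levels, start=1):
            added = level * base_conc
            if added <= 0:
                raise DomainError(
                    f"spike level {level} for {compound} adds nothing; recovery undefined"
                )
            for prep in range(1, n_preparations + 1):
                records.append(
                    {
                        "sample_id": f"spike-L{li}-p{prep}-d{day}-{lab}",
                        "compound": compound,
                        "detector": model.detector_kind,
                        "day": day,
                        "lab": lab,
                        "replicate": prep,
                        "known_conc_mg_per_ml": added,
                        "peak_area": _measure_area(model, base_conc + added, drift, rng),
                        "role": "spike",
                    }
                )
    return pd.DataFrame.from_records(records, columns=PEAK_TABLE_COLUMNS)


def calibration_to_records(
    series: CalibrationSeries, *, sample_prefix: str = "cal"
) -> pd.DataFrame:
    """Peak-table rows (role=calibration) for one calibration series."""
    n = len(series.conc_mg_per_ml)
    return pd.DataFrame(
        {
            "sample_id": [
                f"{sample_prefix}-{series.compound}-d{series.day}-L{i+1}" for i in range(n)
            ],
            "compound": series.compound,
            "detector": series.detector,
            "day": series.day,
            "lab": series.lab,
            "replicate": 1,
            "known_conc_mg_per_ml": series.conc_mg_per_ml,
            "peak_area": series.peak_area,
            "role": "calibration",
        },
        columns=PEAK_TABLE_COLUMNS,
    )


def default_detector_models(
    rel_noise: float = 0.0,
) -> dict[str, dict[str, DetectorModel]]:
    """Generating models per detector/compound from the published regressions.

    ``rel_noise`` sets an approximate relative measurement noise: for PDA the
    additive area SD is ``rel_noise * slope * C_mid`` (scaled to the signal
    span at the midpoint of the calibration range, not to the raw response,
    whose reported intercepts can dominate), and for ELSD the log10-area SD
    is ``rel_noise / ln(10)``, i.e. ~``rel_noise`` multiplicative noise.
    """
    models: dict[str, dict[str, DetectorModel]] = {"PDA": {}, "ELSD": {}}
    for compound, pars in reference.PDA_CALIBRATIONS.items():
        lo, hi = reference.LINEAR_RANGE_MG_PER_ML[compound]
        c_mid = 0.5 * (lo + hi)
        models["PDA"][compound] = DetectorModel(
            detector_kind="PDA",
            slope=pars["slope"],
            intercept=pars["intercept"],
            noise_sd=rel_noise * pars["slope"] * c_mid,
        )
    for compound, pars in reference.ELSD_CALIBRATIONS.items():
        models["ELSD"][compound] = DetectorModel(
            detector_kind="ELSD",
            slope=pars["slope"],
            intercept=pars["intercept"],
            noise_sd=rel_noise / math.log(10.0),
        )
    return models


def default_scenario(seed: int = 0, **overrides) -> Scenario:
    """Scenario with the typical dry-weight contents of Vietnamese-ginseng
    root and the standard 100 mg / 5 mL preparation."""
    kwargs = dict(true_contents=dict(reference.TYPICAL_CONTENT_PCT), seed=seed)
    kwargs.update(overrides)
    return Scenario(**kwargs)


def simulate_study(
    scenario: Scenario,
    models: Mapping[str, Mapping[str, DetectorModel]],
    design: DilutionDesign | None = None,
    *,
    calibration_days: Sequence[int] = (1, 2, 3),
    sample_days: Sequence[int] = (1, 2),
    n_replicates: int = 6,
    labs: Sequence[str] = ("lab1",),
    include_spikes: bool = True,
) -> pd.DataFrame:
    """Simulate a complete study peak table.

    Per detector: one calibration series per compound on each calibration
    day; ``n_replicates`` sample solutions on each sample day in each lab;
    and (optionally) the spike-recovery design on the first sample day.
    All randomness derives from ``scenario.seed``.
    """
    if design is None:
        design = DilutionDesign(c1_by_compound=dict(reference.C1_MG_PER_ML))
    rng = np.random.default_rng(scenario.seed)
    frames = []
    for detector, det_models in models.items():
        for day in calibration_days:
            for compound, model in det_models.items():
                conc = make_dilution_series(design, compound)
                series = simulate_calibration(
                    conc,
                    model,
                    rng,
                    compound=compound,
                    day=day,
                    drift=scenario.drift_factor(day, "lab1", compound),
                )
                frames.append(calibration_to_records(series))
        for lab in labs:
            for day in sample_days:
                frames.append(
                    simulate_sample_set(
                        scenario, det_models, n_replicates, day=day, lab=lab, seed=rng
                    )
                )
            if include_spikes:
                frames.append(
                    make_spike_design(
                        scenario, det_models, day=sample_days[0], lab=lab, seed=rng
                    )
                )
    return pd.concat(frames, ignore_index=True)
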