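"""Configuration, peak-table I/O and run artifacts.

The interchange format is a flat peak-table CSV (comma-separated, UTF-8,
decimal point, mandatory header) with one integrated peak area per row:

    sample_id, compound, detector, day, lab, replicate,
    known_conc_mg_per_ml, peak_area, role

``role`` is one of calibration, sample, spike, blank.
``known_conc_mg_per_ml`` holds the standard concentration for calibration
rows, the *added* concentration for spike rows, and is empty for unknowns.

Run configuration is a pydantic model, loadable from YAML or JSON; every
emitted artifact references the SHA-256 hash of the canonical config JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import reference
from .exceptions import ConfigurationError
from .simulate import PEAK_TABLE_COLUMNS

VALID_ROLES = {"calibration", "sample", "spike", "blank"}


class CompoundConfig(BaseModel):
    """Per-compound standard metadata."""

    purity: float = Field(1.0, gt=0.0, le=1.0)
    c1_mg_per_ml: float = Field(..., gt=0.0)
    true_content_pct: float | None = Field(None, gt=0.0)


class DetectorModelConfig(BaseModel):
    """Generating/response model parameters for one compound on one detector."""

    slope: float = Field(..., gt=0.0)
    intercept: float
    noise_sd: float = Field(0.0, ge=0.0)


class RunConfig(BaseModel):
    """Full pipeline configuration; ``seed`` is mandatory."""

    seed: int
    compounds: dict[str, CompoundConfig]
    dilution_factor: float = Field(reference.DILUTION_FACTOR, gt=0.0, le=1.0)
    n_levels: int = Field(reference.N_LEVELS, ge=2)
    detectors: dict[str, dict[str, DetectorModelConfig]]
    markers: dict[str, dict[str, str]]
    fx_method: Literal["slope", "ratio"] = "slope"
    fx_provenance: Literal["intraday", "interday"] = "intraday"
    volume_ml: float = Field(reference.SAMPLE_VOLUME_ML, gt=0.0)
    mass_mg: float = Field(reference.SAMPLE_MASS_MG, gt=0.0)
    purity_correction: bool = False
    calibration_days: list[int] = Field(default_factory=lambda: [1, 2, 3])
    sample_days: list[int] = Field(default_factory=lambda: [1, 2])
    n_replicates: int = Field(6, ge=1)
    labs: list[str] = Field(default_factory=lambda: ["lab1"])
    day_drift: dict[int, dict[str, float]] = Field(default_factory=dict)
    lab_bias: dict[str, dict[str, float]] = Field(default_factory=dict)
    spike_levels: tuple[float, ...] = (0.8, 1.0, 1.2)
    smd_rule_pct: float = Field(5.00, gt=0.0)

    @field_validator("detectors")
    @classmethod
    def _known_detectors(cls, v):
        bad = set(v) - {"PDA", "ELSD"}
        if bad:
            raise ValueError(f"unknown detectors {sorted(bad)}; expected PDA/ELSD")
        return v

    @model_validator(mode="after")
    def _resolvable(self):
        for detector, mapping in self.markers.items():
            if detector not in self.detectors:
                raise ValueError(f"markers given for unconfigured detector {detector!r}")
            for analyte, marker in mapping.items():
                if analyte not in self.compounds:
                    raise ValueError(f"marker assignment names unknown analyte {analyte!r}")
                if marker not in mapping or mapping[marker] != marker:
                    raise ValueError(
                        f"marker {marker!r} on {detector} must be assigned to itself"
                    )
                if analyte not in self.detectors[detector]:
                    raise ValueError(
                        f"no {detector} response model for analyte {analyte!r}"
                    )
                if marker not in self.detectors[detector]:
                    raise ValueError(
                        f"no {detector} response model for marker {marker!r}"
                    )
        return self


def default_config(seed: int = 0, rel_noise: float = 0.015) -> RunConfig:
    """Bundled scenario: the published five-saponin method with typical
    Vietnamese-ginseng contents and ~1.5% relative measurement noise."""
    from .simulate import default_detector_models

    models = default_detector_models(rel_noise)
    compounds = {
        name: CompoundConfig(
            purity=reference.PURITY[name],
            c1_mg_per_ml=reference.C1_MG_PER_ML[name],
            true_content_pct=reference.TYPICAL_CONTENT_PCT[name],
        )
        for name in reference.COMPOUNDS
    }
    detectors = {
        det: {
            name: DetectorModelConfig(
                slope=m.slope, intercept=m.intercept, noise_sd=m.noise_sd
            )
            for name, m in det_models.items()
        }
        for det, det_models in models.items()
    }
    return RunConfig(
        seed=seed,
        compounds=compounds,
        detectors=detectors,
        markers={k: dict(v) for k, v in reference.MARKER_ASSIGNMENT.items()},
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    raw = json.loads(config.model_dump_json())
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(raw, indent=2, sort_keys=True), encoding="utf-8")


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical (sorted-key) config JSON; changes iff the
    config content changes."""
    canonical = json.dumps(
        json.loads(config.model_dump_json()), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peak-table CSV.

    Raises ConfigurationError naming offending rows (1-based data rows) for
    missing columns, invalid roles, nonpositive ELSD areas and duplicate
    (sample_id, compound, detector, replicate, role) keys.
    """
    df = pd.read_csv(path)
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    df = df[PEAK_TABLE_COLUMNS].copy()

    bad_role = df.index[~df["role"].isin(VALID_ROLES)]
    if len(bad_role):
        raise ConfigurationError(
            f"{path}: invalid role at rows {[int(i) + 1 for i in bad_role[:5]]}"
        )
    elsd_bad = df.index[(df["detector"] == "ELSD") & ~(df["peak_area"] > 0)]
    if len(elsd_bad):
        raise ConfigurationError(
            f"{path}: nonpositive ELSD peak area at rows {[int(i) + 1 for i in elsd_bad[:5]]}"
        )
    dup_mask = df.duplicated(
        subset=["sample_id", "compound", "detector", "replicate", "role"], keep=False
    )
    if dup_mask.any():
        rows = [int(i) + 1 for i in df.index[dup_mask][:5]]
        raise ConfigurationError(f"{path}: duplicate measurement keys at rows {rows}")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=PEAK_TABLE_COLUMNS)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")


@dataclass
class RunLog:
    """Timestamped stage log; every artifact references the config hash."""

    config_hash: str
    software_version: str = "0.1.0"
    stages: list[dict] = dataclass_field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "stages": self.stages,
        }
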