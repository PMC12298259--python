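"""Model/Results interface tying the pipeline together.

``QamsModel`` is built from a peak-table DataFrame plus a ``RunConfig`` —
from a CSV on disk (``from_csv``), an existing frame (constructor) or a
fully synthetic study (``from_config``, which simulates the peak table).
``fit()`` fits all calibration curves, derives the relative conversion
factors both ways, quantifies every unknown by the external-standards
method and by both QAMS variants, and returns a ``QamsResults`` carrying
the estimates, diagnostics and validation tables.

    >>> from qams import QamsModel, default_config
    >>> res = QamsModel.from_config(default_config(seed=1)).fit()
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import calibration as cal
from . import quantify as qc
from . import validation as val
from .exceptions import ConfigurationError
from .io import RunConfig, RunLog, config_hash, read_peak_table, write_json, write_peak_table
from .simulate import (
    CalibrationSeries,
    DetectorModel,
    DilutionDesign,
    Scenario,
    simulate_study,
)

METHOD_ESM = "ESM"
METHOD_QAMS_RATIO = "QAMS_ratio"
METHOD_QAMS_SLOPE = "QAMS_slope"


def _scenario_from_config(config: RunConfig) -> Scenario:
    contents = {
        name: c.true_content_pct
        for name, c in config.compounds.items()
        if c.true_content_pct is not None
    }
    if not contents:
        raise ConfigurationError("config defines no true contents to simulate")
    return Scenario(
        true_contents=contents,
        sample_mass_mg=config.mass_mg,
        volume_ml=config.volume_ml,
        day_drift=config.day_drift,
        lab_bias=config.lab_bias,
        spike_levels=config.spike_levels,
        seed=config.seed,
    )


def _models_from_config(config: RunConfig) -> dict[str, dict[str, DetectorModel]]:
    return {
        det: {
            name: DetectorModel(
                detector_kind=det, slope=m.slope, intercept=m.intercept, noise_sd=m.noise_sd
            )
            for name, m in det_models.items()
        }
        for det, det_models in config.detectors.items()
    }


class QamsModel:
    """Single-marker quantification model over a peak table.

    Parameters
    ----------
    data
        Peak-table DataFrame (see :mod:`qams.io` for the schema).
    config
        Run configuration: compounds, marker assignment, preparation
        constants, F_x provenance, seed.
    """

    def __init__(self, data: pd.DataFrame, config: RunConfig):
        self.data = data.reset_index(drop=True)
        self.config = config
        self.config_hash = config_hash(config)
        self.log = RunLog(config_hash=self.config_hash)

    @classmethod
    def from_csv(cls, path: str | Path, config: RunConfig) -> "QamsModel":
        return cls(read_peak_table(path), config)

    @classmethod
    def from_config(cls, config: RunConfig) -> "QamsModel":
        """Simulate the study the config describes and wrap it in a model."""
        scenario = _scenario_from_config(config)
        models = _models_from_config(config)
        design = DilutionDesign(
            c1_by_compound={n: c.c1_mg_per_ml for n, c in config.compounds.items()},
            dilution_factor=config.dilution_factor,
            n_levels=config.n_levels,
        )
        data = simulate_study(
            scenario,
            models,
            design,
            calibration_days=config.calibration_days,
            sample_days=config.sample_days,
            n_replicates=config.n_replicates,
            labs=config.labs,
        )
        obj = cls(data, config)
        obj.log.record("simulate", rows=len(data), seed=config.seed)
        return obj

    # ------------------------------------------------------------------ fit

    def _effective_conc(self, compound: str, nominal: float) -> float:
        if self.config.purity_correction:
            return nominal * self.config.compounds[compound].purity
        return nominal

    def fit_calibrations(self) -> dict[tuple[str, str, int], cal.CalibrationFit]:
        """Least-squares calibration per (detector, compound, day)."""
        fits: dict[tuple[str, str, int], cal.CalibrationFit] = {}
        calib = self.data[self.data["role"] == "calibration"]
        for (detector, compound, day), grp in calib.groupby(["detector", "compound", "day"]):
            points = [
                cal.CalibrationPoint(
                    concentration=self._effective_conc(compound, float(r.known_conc_mg_per_ml)),
                    peak_area=float(r.peak_area),
                    day=int(day),
                )
                for r in grp.itertuples()
            ]
            fitter = cal.fit_linear if detector == "PDA" else cal.fit_loglog
            fits[(detector, compound, int(day))] = fitter(
                points, compound=compound, detector=detector, day=int(day)
            )
        if not fits:
            raise ConfigurationError("peak table contains no calibration rows")
        return fits

    def _calibration_series(self) -> dict[tuple[str, str, int], CalibrationSeries]:
        out: dict[tuple[str, str, int], CalibrationSeries] = {}
        calib = self.data[self.data["role"] == "calibration"]
        for (detector, compound, day), grp in calib.groupby(["detector", "compound", "day"]):
            grp = grp.sort_values("known_conc_mg_per_ml", ascending=False)
            conc = np.array(
                [self._effective_conc(compound, c) for c in grp["known_conc_mg_per_ml"]]
            )
            out[(detector, compound, int(day))] = CalibrationSeries(
                compound=compound,
                detector=detector,
                conc_mg_per_ml=conc,
                peak_area=grp["peak_area"].to_numpy(dtype=float),
                day=int(day),
            )
        return out

    def _conversion_factors(
        self,
        fits: Mapping[tuple[str, str, int], cal.CalibrationFit],
        series: Mapping[tuple[str, str, int], CalibrationSeries],
    ) -> list[qc.ConversionFactor]:
        """Per-day slope-ratio and response-ratio factors plus inter-day means."""
        factors: list[qc.ConversionFactor] = []
        days = sorted({d for (_, _, d) in fits})
        for detector, mapping in self.config.markers.items():
            domain = "linear" if detector == "PDA" else "log"
            for analyte, marker in mapping.items():
                per_day_slope, per_day_ratio = [], []
                for day in days:
                    kx, ks = (detector, analyte, day), (detector, marker, day)
                    if kx not in fits or ks not in fits:
                        continue
                    per_day_slope.append(qc.fx_slope_ratio(fits[kx], fits[ks]))
                    per_day_ratio.append(qc.fx_response_ratio(series[kx], series[ks], domain))
                factors.extend(per_day_slope)
                factors.extend(per_day_ratio)
                if len(per_day_slope) > 1:
                    factors.append(qc.average_fx(per_day_slope))
                    factors.append(qc.average_fx(per_day_ratio))
        return factors

    def fit(self, fx_provenance: str | None = None) -> "QamsResults":
        """Run calibration, factor derivation and quantification.

        ``fx_provenance`` overrides the config ('intraday' uses the same-day
        factor for each measurement; 'interday' the mean factor across
        calibration days).
        """
        provenance = fx_provenance or self.config.fx_provenance
        if provenance not in {"intraday", "interday"}:
            raise ConfigurationError(f"unknown fx_provenance {provenance!r}")
        fits = self.fit_calibrations()
        series = self._calibration_series()
        factors = self._conversion_factors(fits, series)
        self.log.record("calibrate", n_fits=len(fits))
        self.log.record("factors", n=len(factors))

        def lookup_factor(detector: str, analyte: str, method: str, day: int) -> qc.ConversionFactor:
            for f in factors:
                if (f.detector, f.analyte, f.method) != (detector, analyte, method):
                    continue
                if provenance == "intraday" and f.provenance == f"intra_day({day})":
                    return f
                if provenance == "interday" and f.provenance.startswith("inter_day_mean"):
                    return f
            # single calibration day: fall back to the lone intra-day factor
            if provenance == "interday":
                cands = [
                    f
                    for f in factors
                    if (f.detector, f.analyte, f.method) == (detector, analyte, method)
                    and f.provenance.startswith("intra_day")
                ]
                if len(cands) == 1:
                    return cands[0]
            raise ConfigurationError(
                f"no {method} factor for {analyte} on {detector}, day {day} ({provenance})"
            )

        # fresh single-marker measurement: the marker's top calibration level
        # of the measurement's day
        marker_meas: dict[tuple[str, str, int], tuple[float, float]] = {}
        calib = self.data[self.data["role"] == "calibration"]
        for (detector, compound, day), grp in calib.groupby(["detector", "compound", "day"]):
            top = grp.loc[grp["known_conc_mg_per_ml"].idxmax()]
            marker_meas[(detector, compound, int(day))] = (
                float(top["peak_area"]),
                self._effective_conc(compound, float(top["known_conc_mg_per_ml"])),
            )

        def nearest_cal_day(detector: str, compound: str, day: int) -> int:
            """The measurement day's own calibration if present, else the
            closest (preferring earlier) calibration day — the stored-curve
            situation that lets response drift surface as nonzero SMD."""
            days_avail = sorted(d for (det, comp, d) in fits if (det, comp) == (detector, compound))
            if not days_avail:
                raise ConfigurationError(f"no calibration for {compound} on {detector}")
            if day in days_avail:
                return day
            return min(days_avail, key=lambda d: (abs(d - day), d > day))

        unknowns = self.data[self.data["role"].isin(["sample", "spike"])]
        records = []
        for row in unknowns.itertuples():
            detector, compound, day = row.detector, row.compound, int(row.day)
            mapping = self.config.markers.get(detector, {})
            if compound not in mapping:
                continue  # not quantifiable on this detector (e.g. no response)
            marker = mapping[compound]
            cal_day = nearest_cal_day(detector, compound, day)
            fit_x = fits[(detector, compound, cal_day)]
            fit_s = fits[(detector, marker, nearest_cal_day(detector, marker, day))]
            area_s, conc_s = marker_meas[(detector, marker, fit_s.day)]
            a_x = float(row.peak_area)

            if detector == "PDA":
                conc_esm = qc.esm_conc_linear(a_x, fit_x)
                f_ratio = lookup_factor(detector, compound, "response_ratio", cal_day)
                conc_ratio = qc.qams_conc_linear(a_x, area_s, conc_s, f_ratio)
                f_slope = lookup_factor(detector, compound, "slope_ratio", cal_day)
                conc_slope = qc.qams_conc_linear(
                    a_x,
                    area_s,
                    conc_s,
                    f_slope,
                    intercept_x=fit_x.intercept,
                    intercept_s=fit_s.intercept,
                )
            else:
                conc_esm = qc.esm_conc_log(a_x, fit_x)
                conc_s_ug = conc_s * cal.UG_PER_MG
                f_ratio = lookup_factor(detector, compound, "response_ratio", cal_day)
                conc_ratio = qc.qams_conc_log(a_x, area_s, conc_s_ug, f_ratio)
                f_slope = lookup_factor(detector, compound, "slope_ratio", cal_day)
                conc_slope = qc.qams_conc_log(
                    a_x,
                    area_s,
                    conc_s_ug,
                    f_slope,
                    intercept_x=fit_x.intercept,
                    intercept_s=fit_s.intercept,
                )

            added_pct = np.nan
            if row.role == "spike" and np.isfinite(row.known_conc_mg_per_ml):
                added_pct = qc.content_percent(
                    float(row.known_conc_mg_per_ml), self.config.volume_ml, self.config.mass_mg
                )
            for method, conc in (
                (METHOD_ESM, conc_esm),
                (METHOD_QAMS_RATIO, conc_ratio),
                (METHOD_QAMS_SLOPE, conc_slope),
            ):
                records.append(
                    {
                        "sample_id": row.sample_id,
                        "compound": compound,
                        "detector": detector,
                        "day": day,
                        "lab": row.lab,
                        "replicate": int(row.replicate),
                        "role": row.role,
                        "method": method,
                        "marker": marker,
                        "conc_mg_per_ml": conc,
                        "content_pct": qc.content_percent(
                            conc, self.config.volume_ml, self.config.mass_mg
                        ),
                        "in_range": fit_x.in_range(conc),
                        "added_content_pct": added_pct,
                    }
                )
        quant = pd.DataFrame.from_records(records)
        self.log.record("quantify", n=len(quant))
        return QamsResults(
            model=self,
            calibrations=dict(fits),
            factors=factors,
            quant=quant,
            fx_provenance=provenance,
        )


@dataclass
class QamsResults:
    """Fitted calibrations, conversion factors and quantification tables."""

    model: QamsModel
    calibrations: dict[tuple[str, str, int], cal.CalibrationFit]
    factors: list[qc.ConversionFactor]
    quant: pd.DataFrame
    fx_provenance: str = "intraday"

    # ------------------------------------------------------------- tables

    def calibration_table(self) -> pd.DataFrame:
        rows = []
        for (detector, compound, day), f in sorted(self.calibrations.items()):
            lod, loq = cal.lod_loq(f)
            rows.append(
                {
                    "detector": detector,
                    "compound": compound,
                    "day": day,
                    "model_kind": f.model_kind,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r": f.r,
                    "residual_sd": f.residual_sd,
                    "slope_se": f.slope_se,
                    "n_points": f.n_points,
                    "conc_unit": f.conc_unit,
                    "range_lo_mg_per_ml": f.valid_range[0],
                    "range_hi_mg_per_ml": f.valid_range[1],
                    "lod_mg_per_ml": lod,
                    "loq_mg_per_ml": loq,
                }
            )
        return pd.DataFrame(rows)

    def fx_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "detector": f.detector,
                    "analyte": f.analyte,
                    "marker": f.marker,
                    "method": f.method,
                    "provenance": f.provenance,
                    "fx": f.value,
                    "fx_2dp": val.round2(f.value),
                }
                for f in self.factors
            ]
        )

    # --------------------------------------------------------- validation

    def sample_quant(self) -> pd.DataFrame:
        return self.quant[self.quant["role"] == "sample"].copy()

    def comparison(self, rule_pct: float | None = None) -> val.ComparisonReport:
        """SMD of each QAMS variant against the ESM baseline, per replicate."""
        rule = self.model.config.smd_rule_pct if rule_pct is None else rule_pct
        return val.compare_methods(self.sample_quant(), rule_pct=rule)

    def precision(self, mode: str = "pooled") -> pd.DataFrame:
        return val.precision_summary(self.sample_quant(), mode=mode)

    def recovery(self) -> pd.DataFrame:
        """Spike recoveries, matched to base-sample contents of the same
        day and laboratory."""
        spiked = self.quant[self.quant["role"] == "spike"]
        if spiked.empty:
            raise ConfigurationError("no spike rows in the quantification table")
        samples = self.sample_quant()
        frames = []
        for (day, lab), grp in spiked.groupby(["day", "lab"]):
            base = (
                samples[(samples["day"] == day) & (samples["lab"] == lab)]
                .groupby(["compound", "detector", "method"], as_index=False)["content_pct"]
                .mean()
            )
            frames.append(val.recovery_summary(grp, base))
        return pd.concat(frames, ignore_index=True)

    # ------------------------------------------------------------ summary

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "QAMS single-marker quantification results",
            "=" * 57,
            f"config hash     : {self.model.config_hash[:16]}",
            f"seed            : {cfg.seed}",
            f"F_x provenance  : {self.fx_provenance}",
            f"calibration fits: {len(self.calibrations)} "
            f"(days {sorted({d for *_, d in self.calibrations})})",
            "",
            "Relative conversion factors (F_x, 2 dp)",
            "-" * 57,
        ]
        fx = self.fx_table()
        agg = (
            fx.groupby(["detector", "analyte", "marker", "method"])["fx"]
            .mean()
            .reset_index()
        )
        for r in agg.itertuples():
            lines.append(
                f"  {r.detector:<5} {r.analyte:>6} / {r.marker:<6} "
                f"{r.method:<15} {val.round2(r.fx):.2f}"
            )
        try:
            comp = self.comparison()
            lines += ["", f"Method comparison (SMD rule <= {comp.rule_pct:.2f}%)", "-" * 57]
            for r in comp.table.itertuples():
                flag = "pass" if r.passed else "FAIL"
                lines.append(
                    f"  {r.detector:<5} {r.compound:>6} {r.method:<11} "
                    f"H_ESM {r.h_esm_mean:6.2f}+/-{r.h_esm_sd:.2f}  "
                    f"H_QAMS {r.h_qams_mean:6.2f}+/-{r.h_qams_sd:.2f}  "
                    f"SMD {r.smd_mean:6.2f}+/-{r.smd_sd:.2f}  [{flag}]"
                )
        except ConfigurationError:
            pass
        return "\n".join(lines)

    # ---------------------------------------------------------- artifacts

    def save_artifacts(self, outdir: str | Path) -> dict[str, str]:
        """Write the full artifact bundle; returns artifact name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.model.config_hash
        paths = {}

        calib = self.calibration_table()
        write_json(
            {"config_hash": h, "fits": calib.to_dict(orient="records")},
            outdir / "calibration.json",
        )
        paths["calibration"] = str(outdir / "calibration.json")

        write_json(
            {"config_hash": h, "factors": self.fx_table().to_dict(orient="records")},
            outdir / "conversion_factors.json",
        )
        paths["factors"] = str(outdir / "conversion_factors.json")

        self.quant.to_csv(outdir / "quantification.csv", index=False)
        paths["quant"] = str(outdir / "quantification.csv")

        report = {"config_hash": h}
        comp = self.comparison()
        report["comparison"] = comp.table.to_dict(orient="records")
        report["smd_rule_pct"] = comp.rule_pct
        report["all_pass"] = comp.all_pass
        try:
            report["precision"] = self.precision().to_dict(orient="records")
        except ConfigurationError:
            report["precision"] = []
        try:
            rec = self.recovery()
            report["recovery"] = rec.to_dict(orient="records")
            rec.to_csv(outdir / "recovery.csv", index=False)
        except ConfigurationError:
            report["recovery"] = []
        write_json(report, outdir / "validation_report.json")
        comp.table.to_csv(outdir / "comparison.csv", index=False)
        paths["report"] = str(outdir / "validation_report.json")

        self.model.log.record("artifacts", outdir=str(outdir))
        write_json(self.model.log.to_dict(), outdir / "run_log.json")
        write_peak_table(self.model.data, outdir / "peak_table.csv")
        return paths

    def plot_calibration(self, detector: str, compound: str, day: int = 1, ax=None):
        """Optional diagnostic: calibration points and fitted line."""
        import matplotlib.pyplot as plt

        fit = self.calibrations[(detector, compound, day)]
        series = self.model.data.query(
            "role == 'calibration' and detector == @detector"
            " and compound == @compound and day == @day"
        )
        if ax is None:
            _, ax = plt.subplots()
        x = series["known_conc_mg_per_ml"].to_numpy(dtype=float)
        y = series["peak_area"].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 50)
        if fit.model_kind == "linear":
            ax.plot(x, y, "o", grid, fit.slope * grid + fit.intercept, "-")
            ax.set_xlabel("concentration (mg/mL)")
            ax.set_ylabel("peak area")
        else:
            ax.loglog(x * 1000, y, "o", grid * 1000, fit.predict_area(grid), "-")
            ax.set_xlabel("concentration (ug/mL)")
            ax.set_ylabel("peak area")
        ax.set_title(f"{compound} on {detector}, day {day} (R={fit.r:.4f})")
        return ax
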