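"""Method-validation battery: precision RSDs, spike recovery, and the
standard-method-difference (SMD) comparison of QAMS against the external
standards method.

SMD(%) = |H_ESM - H_QAMS| / H_ESM * 100; values at or below 5.00% indicate
no significant difference between the indirect and the direct quantification.
SMD is computed per replicate sample and then summarised as mean +/- SD,
which is why a table's mean SMD can differ slightly from the SMD of the
table's mean contents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

#: Agreement threshold for the SMD criterion, in percent.
SMD_RULE_PCT = 5.00


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (report convention)."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


def smd(h_esm: float, h_qams: float) -> float:
    """Standard method difference |H_ESM - H_QAMS| / H_ESM * 100, in %."""
    if h_esm <= 0:
        raise DomainError(f"ESM content must be positive, got {h_esm}")
    return abs(h_esm - h_qams) / h_esm * 100.0


def rsd(values: Sequence[float] | np.ndarray) -> float:
    """Relative standard deviation, sample SD / mean * 100 (%)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("RSD needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise DomainError("RSD undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


def recovery(found_spiked: float, found_base: float, added: float) -> float:
    """Spike recovery (found - base) / added * 100, in %."""
    if added <= 0:
        raise DomainError(f"added amount must be positive, got {added}")
    return (found_spiked - found_base) / added * 100.0


@dataclass(frozen=True)
class ComparisonReport:
    """Per-(compound, detector, method) SMD summary with pass/fail flags."""

    table: pd.DataFrame
    rule_pct: float = SMD_RULE_PCT

    @property
    def all_pass(self) -> bool:
        return bool(self.table["passed"].all())


def precision_summary(
    quant: pd.DataFrame,
    *,
    mode: Literal["pooled", "day_means"] = "pooled",
) -> pd.DataFrame:
    """Intra-day, inter-day and inter-laboratory RSDs of contents.

    ``quant`` must carry columns compound, detector, method, day, lab,
    content_pct.  Intra-day RSD is computed per (day, lab); inter-day RSD on
    the values pooled across days within a lab; inter-laboratory RSD on the
    values pooled across labs.  ``mode="day_means"`` instead takes the RSD
    of per-day (per-lab) mean contents for the pooled groupings.
    """
    required = {"compound", "detector", "method", "day", "lab", "content_pct"}
    missing = required - set(quant.columns)
    if missing:
        raise ConfigurationError(f"quant table lacks columns: {sorted(missing)}")
    if quant.empty:
        raise ConfigurationError("empty quantification table")

    rows = []
    for (compound, detector, method), grp in quant.groupby(
        ["compound", "detector", "method"], sort=True
    ):
        for (day, lab), sub in grp.groupby(["day", "lab"]):
            rows.append(
                {
                    "compound": compound,
                    "detector": detector,
                    "method": method,
                    "grouping": "intra_day",
                    "day": day,
                    "lab": lab,
                    "n": len(sub),
                    "rsd_pct": rsd(sub["content_pct"]),
                }
            )
        for lab, sub in grp.groupby("lab"):
            if sub["day"].nunique() < 2:
                continue
            if mode == "pooled":
                values = sub["content_pct"]
            else:
                values = sub.groupby("day")["content_pct"].mean()
            rows.append(
                {
                    "compound": compound,
                    "detector": detector,
                    "method": method,
                    "grouping": "inter_day",
                    "day": None,
                    "lab": lab,
                    "n": len(values),
                    "rsd_pct": rsd(values),
                }
            )
        if grp["lab"].nunique() >= 2:
            if mode == "pooled":
                values = grp["content_pct"]
            else:
                values = grp.groupby("lab")["content_pct"].mean()
            rows.append(
                {
                    "compound": compound,
                    "detector": detector,
                    "method": method,
                    "grouping": "inter_laboratory",
                    "day": None,
                    "lab": None,
                    "n": len(values),
                    "rsd_pct": rsd(values),
                }
            )
    return pd.DataFrame(rows)


def compare_methods(
    quant: pd.DataFrame,
    *,
    rule_pct: float = SMD_RULE_PCT,
    baseline: str = "ESM",
) -> ComparisonReport:
    """SMD comparison of each QAMS variant against the ESM baseline.

    ``quant`` must carry compound, detector, method, sample_id, content_pct
    (one row per replicate sample and method).  SMD is computed per
    replicate sample, then summarised as mean +/- SD per
    (compound, detector, method); a group passes iff its mean SMD is at or
    below ``rule_pct``.
    """
    methods = set(quant["method"].unique())
    if baseline not in methods:
        raise ConfigurationError(f"baseline method {baseline!r} absent from results")
    qams_methods = sorted(methods - {baseline})
    if not qams_methods:
        raise ConfigurationError("no QAMS variant present to compare against the baseline")

    wide = quant.pivot_table(
        index=["compound", "detector", "sample_id"],
        columns="method",
        values="content_pct",
        aggfunc="mean",
    )
    rows = []
    for (compound, detector), grp in wide.groupby(level=["compound", "detector"]):
        h_esm = grp[baseline].dropna()
        for method in qams_methods:
            if method not in grp or grp[method].dropna().empty:
                continue
            paired = grp[[baseline, method]].dropna()
            smds = np.array(
                [smd(e, q) for e, q in zip(paired[baseline], paired[method])]
            )
            rows.append(
                {
                    "compound": compound,
                    "detector": detector,
                    "method": method,
                    "n": len(paired),
                    "h_esm_mean": float(h_esm.mean()),
                    "h_esm_sd": float(h_esm.std(ddof=1)) if len(h_esm) > 1 else 0.0,
                    "h_qams_mean": float(paired[method].mean()),
                    "h_qams_sd": float(paired[method].std(ddof=1)) if len(paired) > 1 else 0.0,
                    "smd_mean": float(smds.mean()),
                    "smd_sd": float(smds.std(ddof=1)) if len(smds) > 1 else 0.0,
                    "passed": bool(smds.mean() <= rule_pct),
                }
            )
    return ComparisonReport(table=pd.DataFrame(rows), rule_pct=rule_pct)


def recovery_summary(
    spiked_quant: pd.DataFrame,
    base_contents: pd.DataFrame,
) -> pd.DataFrame:
    """Per-spike recovery table.

    ``spiked_quant`` carries one row per spiked preparation and method with
    columns compound, detector, method, sample_id, content_pct and
    added_content_pct; ``base_contents`` carries the unspiked sample's mean
    content per (compound, detector, method) in column content_pct.
    """
    base = base_contents.set_index(["compound", "detector", "method"])["content_pct"]
    rows = []
    for _, rec in spiked_quant.iterrows():
        key = (rec["compound"], rec["detector"], rec["method"])
        if key not in base.index:
            raise ConfigurationError(f"no base content for {key}")
        rows.append(
            {
                "compound": rec["compound"],
                "detector": rec["detector"],
                "method": rec["method"],
                "sample_id": rec["sample_id"],
                "added_content_pct": rec["added_content_pct"],
                "found_content_pct": rec["content_pct"],
                "recovery_pct": recovery(
                    rec["content_pct"], float(base.loc[key]), rec["added_content_pct"]
                ),
            }
        )
    return pd.DataFrame(rows)
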