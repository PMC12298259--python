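"""Published reference method parameters for the five Vietnamese-ginseng saponins.

These are the regression equations, stock concentrations, marker assignments
and standard purities of the validated HPLC-PDA/ELSD method for *Panax
vietnamensis* root: ginsenosides Rb1, Rd and Rg1 (PPD/PPT dammarane types)
and the ocotillol-type majonoside R2 and vina-ginsenoside R2.

Conventions
-----------
* PDA calibration is linear in concentration expressed in mg/mL:
  ``area = a * C + b``.
* ELSD calibration is a power law, fitted linearly in log10-log10
  coordinates with concentration expressed in ug/mL:
  ``log10(area) = a * log10(C_ug) + b``.

Vina-ginsenoside R2 has no usable PDA response (no chromophore) and
ginsenoside Rd falls below the ELSD quantification limit, so each detector
quantifies four of the five compounds.
"""

from __future__ import annotations

COMPOUNDS = ["G-Rb1", "G-Rd", "G-Rg1", "M-R2", "V-R2"]

#: Dammarane skeleton class per compound (PPD/PPT carry the UV-active
#: side-chain double bond; OT saponins do not).
SAPONIN_TYPE = {
    "G-Rb1": "PPD",
    "G-Rd": "PPD",
    "G-Rg1": "PPT",
    "M-R2": "OT",
    "V-R2": "OT",
}

#: Certified purity (mass fraction) of each primary reference standard.
PURITY = {
    "G-Rb1": 0.9917,
    "G-Rd": 0.9448,
    "G-Rg1": 0.9643,
    "M-R2": 0.9886,
    "V-R2": 0.9763,
}

#: Stock (level-1) standard concentrations in mg/mL; levels 2-6 follow by
#: serial dilution with factor 0.75.
C1_MG_PER_ML = {
    "G-Rb1": 0.36,
    "G-Rd": 0.17,
    "G-Rg1": 1.39,
    "M-R2": 2.30,
    "V-R2": 0.81,
}

DILUTION_FACTOR = 0.75
N_LEVELS = 6

#: Reported PDA regression parameters (slope in area per mg/mL, intercept in
#: area units) and correlation coefficient R.
PDA_CALIBRATIONS = {
    "G-Rg1": {"slope": 13426.0, "intercept": 846186.0, "r": 0.9998},
    "M-R2": {"slope": 374.0, "intercept": 14146.0, "r": 0.9999},
    "G-Rb1": {"slope": 10175.0, "intercept": 50838.0, "r": 0.9999},
    "G-Rd": {"slope": 11035.0, "intercept": 17292.0, "r": 1.0000},
}

#: Reported ELSD log10-log10 regression parameters (unitless slope,
#: log10-area intercept; concentration in ug/mL) and R.
ELSD_CALIBRATIONS = {
    "G-Rg1": {"slope": 1.3722, "intercept": 1.0728, "r": 0.9999},
    "M-R2": {"slope": 1.3223, "intercept": 1.2472, "r": 0.9996},
    "V-R2": {"slope": 1.3942, "intercept": 1.0544, "r": 0.9999},
    "G-Rb1": {"slope": 1.4371, "intercept": 0.9450, "r": 0.9998},
    "G-Rd": {"slope": 1.1121, "intercept": 1.3828, "r": 0.9937},
}

#: Single-marker assignment per detector: analyte -> marker.  On the PDA,
#: ginsenoside Rb1 serves all four UV-quantifiable saponins; on the ELSD,
#: Rb1 serves the PPD/PPT pair and majonoside R2 the ocotillol pair.
MARKER_ASSIGNMENT = {
    "PDA": {
        "G-Rb1": "G-Rb1",
        "G-Rd": "G-Rb1",
        "G-Rg1": "G-Rb1",
        "M-R2": "G-Rb1",
    },
    "ELSD": {
        "G-Rb1": "G-Rb1",
        "G-Rg1": "G-Rb1",
        "M-R2": "M-R2",
        "V-R2": "M-R2",
    },
}

#: Reported linear ranges in mg/mL (lower bound = C1 * 0.75**5 rounded to
#: 2 dp, upper bound = C1).
LINEAR_RANGE_MG_PER_ML = {
    "G-Rg1": (0.33, 1.39),
    "M-R2": (0.55, 2.30),
    "V-R2": (0.19, 0.81),
    "G-Rb1": (0.09, 0.36),
    "G-Rd": (0.04, 0.17),
}

#: Mean dry-weight contents (% of dried root) observed with the external
#: standards method; used as the default true contents of the synthetic
#: scenario so simulated samples land in the method's working range.
TYPICAL_CONTENT_PCT = {
    "G-Rb1": 1.46,
    "G-Rd": 0.96,
    "G-Rg1": 3.96,
    "M-R2": 5.71,
    "V-R2": 2.67,
}

#: Sample preparation constants: extract volume (mL) and dry sample mass (mg).
SAMPLE_VOLUME_ML = 5.0
SAMPLE_MASS_MG = 100.0
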