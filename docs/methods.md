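# Methods

## Scope and data model

The package operates on integrated peak areas only. A study is a flat table
of measurements — calibration standards, replicate sample solutions, spiked
samples — tagged with compound, detector (PDA or ELSD), day, laboratory and
replicate. No retention times, peak shapes or raw chromatograms are modelled;
peak integration is assumed to have happened upstream.

Five saponins of Vietnamese-ginseng root are bundled as the reference
method: ginsenosides Rb1 and Rd (PPD type), Rg1 (PPT type), and the
ocotillol pair majonoside R2 and vina-ginsenoside R2. Vina-ginsenoside R2
has no usable UV response (no chromophore), and ginsenoside Rd falls below
the ELSD quantification limit, so each detector quantifies four of the five.
The bundled marker assignment uses Rb1 for the PPD/PPT saponins on both
detectors and majonoside R2 for the ocotillol pair on the ELSD.

## Response models and calibration

* PDA: `A = a·C + b`, `C` in mg/mL, ordinary least squares, unweighted.
* ELSD: `log10 A = a·log10 C + b`, `C` in µg/mL, OLS in log-log coordinates.

The canonical storage unit is mg/mL everywhere; the log-log fitter converts
to µg/mL internally, which is why its inversion carries the `−3` term
(`C_mg = 10^((log10 A − b)/a − 3)`). All logarithms are base 10 — required
for that unit offset to be exactly 3·a in the intercept. The correlation
coefficient is reported as *R*, not R², matching analytical-chemistry
reporting convention. No weighting and no outlier rejection are applied.

LOD/LOQ use the ICH residual-SD formulation, 3.3 σ/a and 10 σ/a, because the
data model has no raw noise traces to support a signal-to-noise definition.
For log-log fits the ratio is formed in the log domain and back-transformed,
`LOD = 10^(3.3 σ/a − 3)` mg/mL; note this tends to 1 µg/mL (the `log C = 0`
point), not zero, as σ → 0 — a known artefact of defining a detection limit
for a power-law response, and one reason reported ELSD LOD/LOQ values are
not meaningfully comparable across formulations.

## Conversion factors

Two constructions per detector domain:

* **Slope ratio** `F_x = a_x/a_s` from same-day calibration fits.
* **Response ratio**: per matched dilution level *i*,
  `(A_x,i/C_x,i)/(A_s,i/C_s,i)` (linear) or
  `(log10 A_x,i/log10 C_x,i)/(log10 A_s,i/log10 C_s,i)` (log, µg/mL),
  averaged arithmetically over levels. Matched-level pairing was chosen
  because it reproduces the published log-domain factors (0.94, 0.93, 0.97,
  1.04) exactly at two decimals from the published regression lines.

Inter-day factors are the arithmetic mean of per-day factors (not the ratio
of averaged slopes); the two differ only in the third decimal on synthetic
data, and the provenance string in every emitted factor records which was
used.

## QAMS operating mode

The intercept-aware equations consume *stored* analyte parameters
(`b_x`, and `F_x`) together with a *fresh* measurement of the marker
standard `(A_s, C_s)` — in the pipeline, the marker's top calibration level
of the measurement day. This is the reading under which single-marker
quantification is operationally meaningful: only the marker standard needs
to be injected on the analysis day. Two consequences worth stating:

* When the marker measurement lies on the marker's own calibration line and
  `F_x = a_x/a_s`, the slope-factor equations reproduce the ESM inversion
  *exactly* (algebraic identity; the test suite checks it to machine
  precision for every pairing). Nonzero slope-factor SMD therefore isolates
  genuine inconsistency — response drift between the stored parameters and
  the analysis day, which the simulator can inject as a per-day
  multiplicative factor.
* The intercept-free variants are exact only for measurements that coincide
  with the marker injection itself; against a separate marker standard they
  carry a concentration-dependent bias even noise-free (several percent for
  the marker's own samples, tens of percent for cross-type analytes on the
  PDA, whose published intercepts are large relative to the signal). This is
  the quantitative argument for fixing `F_x` from slopes.

Out-of-range concentrations are flagged (`in_range=False`), never clamped;
exclusion decisions are left to the caller, mirroring how a compound that
fails its quantification limit is dropped from a detector rather than
truncated.

## Synthetic data

The generator emulates the study design the analysis assumes:

* **Dilution series**: six levels, factor 0.75, per-compound stocks
  (0.36, 0.17, 1.39, 2.30, 0.81 mg/mL); level *i* is `C1·0.75^(i−1)`.
* **Noise**: additive Gaussian on area for PDA; Gaussian on log10-area for
  ELSD (multiplicative on area, keeping areas positive). The default
  `rel_noise = 0.015` sets the PDA area SD to 1.5% of the *signal term*
  `a·C` at mid-range — not of the full response, whose published intercepts
  can dwarf the signal — and the ELSD log-SD to `0.015/ln 10`, i.e. ~1.5%
  multiplicative. These land simulated intra-day RSDs in the 0.3–3% band
  typical of validated HPLC assays.
* **Contents**: defaults are the typical dry-weight contents of the root
  (1.46, 0.96, 3.96, 5.71, 2.67% for Rb1, Rd, Rg1, M-R2, V-R2), inverted to
  solution concentrations through `C = H·m/(100·V)` with the standard
  100 mg / 5 mL preparation. Rd's typical content maps to 0.192 mg/mL,
  marginally above its PDA calibration range — the pipeline flags those
  results, reflecting the same tension present in real data.
* **Structure**: three calibration days, two sample days × six replicate
  preparations, optional second laboratory, and a 3-level × 3-preparation
  spike design (80/100/120% of nominal content; the added concentration is
  recorded in the peak table's known-concentration column).
* **Drift**: per-(day, compound) and per-(lab, compound) multiplicative
  response factors, default 1.0. Real inter-day variation has no published
  mechanism; a multiplicative factor is the simplest model that reproduces
  the stored-parameter failure mode of slope-factor QAMS under inter-day
  provenance.

What the generator does *not* emulate: integration error correlated across
co-eluting peaks, heteroscedasticity beyond the two noise laws, calibration
curvature, carry-over, or matrix effects. Passing tests therefore establish
the *calculus* — calibration, factors, quantification, validation
statistics — not instrument behaviour.

Determinism: a scenario's seed fully determines every draw; identical
config + seed gives byte-identical artifacts.

## Validation statistics

* RSD = sample SD / mean × 100 (n ≥ 2).
* Intra-day RSD per (day, lab); inter-day and inter-laboratory RSDs on the
  pooled individual results (n = 12 by default), with an `of-day-means`
  alternative exposed as an option but not default.
* Recovery = (found − base)/added × 100, base taken as the mean unspiked
  content of the same day/lab and method.
* SMD computed per replicate then averaged (mean ± SD); this is why a
  table's mean SMD differs slightly from the SMD of its mean contents
  (27.67 vs a printed 27.65 in one published example). The pass rule is
  mean SMD ≤ 5.00%.

Reported factors, contents and SMDs are rounded to two decimals (halves
away from zero); all internal computation is at full precision.

## Numerical and design choices

* Fits require ≥ 3 distinct concentrations; degenerate designs raise
  rather than return NaN.
* Division guards: zero marker slope, marker area equal to its intercept,
  `log10 C_s = 0` (the 1 µg/mL singularity of the log-domain equations) all
  raise domain errors naming the offending quantity.
* Samples measured on a day without its own calibration fall back to the
  nearest (preferring earlier) calibration day — the stored-curve situation.
* Purity correction of standard concentrations (certified purities 94.5–99.2%)
  is available but OFF by default, since published stock concentrations are
  not stated to be purity-corrected.
* Problem sizes in the test and acceptance runs (six-level series, three
  days, six replicates) match the reference study design; everything runs
  in seconds on one core.

## Known limitations

* The PDA response-ratio factors computed from the published regression
  parameters disagree with the published PDA response-ratio values; the
  published intercepts are too large relative to the slopes for the two to
  be mutually consistent, so those factors are reported but not treated as
  reproducible reference values.
* No uncertainty propagation through `F_x`: uncertainties are empirical SDs
  across replicates, as in standard method-validation practice.
* The 5.00% SMD rule is a field heuristic, not a hypothesis test; no formal
  equivalence testing is implemented.
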