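# Methods

This note documents the models, defaults, and numerical choices behind
`ventplume`, and what the synthetic-data tests do and do not demonstrate
about real survey data.

## Water-column processing

CTD casts are ordered records of depth (meters below sea level, positive
downward — the convention throughout), temperature, salinity, and
optionally potential density anomaly (σ₀), turbidity, and redox
potential offset. When σ₀ is absent it is derived from T/S with the
EOS-80 one-atmosphere density polynomial (Millero & Poisson 1981) at
surface reference pressure; at the millikelvin-scale precision of plume
anomalies any standard seawater equation of state gives indistinguishable
gradients, and the implementation is verified against the published
check values of that polynomial.

**Backgrounds.** The background profile of a property is fitted from
reference casts by per-depth-bin statistics (default bin width 50 m):
each cast contributes its in-bin median, the background is the median of
those per-cast medians, and the residual SD is their n−1 standard
deviation across casts. Medians keep the fit robust if a reference cast
clips the plume edge. Interpolation between bin centers is linear and
the profile refuses to extrapolate outside the covered depth range.

**Anomalies and delineation.** Anomalies are observed minus background
at matched depths, sign preserved (redox anomalies are negative).
The plume interval is the longest contiguous run of |anomaly| above a
threshold — either absolute or k× the local residual SD (default k=3,
since a plume signal is far above instrument noise); equal-length runs
tie-break to the deepest run because plumes are bottom-sourced.

**Stratification.** N² = (g/ρ₀)·dρ/d(depth) with the gradient from a
least-squares line over the requested window (≥3 density records). With
depth positive down, stable water gives a positive gradient and a real
N. A negative N² returns N=0 with a warning; exact zero (uniform
density) returns 0 silently.

## Plume-rise inversion

The Morton–Taylor–Turner maximum rise height in a linearly stratified
ambient, z_max = C·F₀^{1/4}·N^{−3/4}, is inverted to
F₀ = (z_max/C)⁴·N³. The coefficient C defaults to 3.76 (the
spreading/neutral-height form common in hydrothermal plume studies) and
is configurable. Heat flux follows as P = F₀·ρ·c_p/(g·α) and the fluid
volume flux as Q = P/(ρ·c_p·ΔT)·86 400, ΔT being the
endmember-minus-ambient contrast in kelvin. Default constants
ρ = 1028 kg m⁻³, c_p = 3900 J kg⁻¹ K⁻¹, g = 9.81 m s⁻², α = 1×10⁻⁴ K⁻¹;
this set reproduces the canonical 24 MW ↔ ~1,400 m³ d⁻¹ pairing for a
370 °C black-smoker fluid in −0.8 °C bottom water. All constants are
recorded in the result's assumptions for provenance. Published
power/volume-flux pairs that mix differently rounded constants cannot
all be reproduced by one consistent set; the library computes, it does
not fit, and callers choose the constants. Interfaces accept °C and
convert internally; only differences enter the physics.

## Endmember reconstruction and fluxes

Dilution treats heat as the conservative tracer:
D = (T_end − T_amb)/ΔT_sample. Both the endmember/ambient temperature
pair and a direct temperature-excess form are exposed, since published
tables sometimes quote the excess alone. The endmember concentration is
(plume − background)·D (nM → mM via 10⁻⁶). Background subtraction
defaults to the reference-water mean of the species — the
conservative-mixing-correct choice — with a zero-background mode for
projecting printed maxima. Table-level estimation computes a per-sample
dilution and projection and aggregates by the median, which is robust to
the strongly right-skewed dilution distribution; a `max` mode projects
the most concentrated sample at the minimum dilution, the shipboard
first-look convention. Daily flux is Q × endmember (mM ≡ mol m⁻³);
annual tonnage uses 365.25 d yr⁻¹ and a built-in molar-mass table
(CH₄ 16.043, H₂ 2.016, Fe 55.845, Mn 54.938 g mol⁻¹). When H₂ was not
measured, an endmember can be imputed from CH₄ at a configurable molar
H₂:CH₄ ratio (default 10, typical of high-temperature fluids) and is
flagged as assumed.

## Mixing diagnostics

`conservative_regression` fits OLS of species vs tracer (δ³He by
default) and reports slope, intercept, r, and two flags:

* **conservative** — the intercept is statistically indistinguishable
  from the background concentration (two-sided t, default α = 0.05);
  a conservative mixing line must hit the background at zero tracer.
* **consumed** — the vent-anchored slope collapses at the dilute end.
  Each tercile of the tracer range defines a slope by the ratio
  estimator R = Σ(y − background)/Σx; the statistic is a Welch-type t
  contrasting R of the lowest-tracer tercile against R of the
  highest-tracer tercile (the vent end, least affected by consumption),
  with ratio-estimator variances. Those variances diverge as a
  tercile's tracer signal vanishes, so noise-dominated near-background
  samples cannot fake a shortfall. The earlier, more obvious choice —
  extrapolating an unconstrained OLS line from the high tercile — is
  *not* used: with strong first-order loss the high tercile itself
  curves, the fitted slope oversteepens, and the extrapolation
  undershoots so badly that consumed gases look enriched.

Samples from the buoyant plume stem are excluded by default: that water
rises in about an hour and consumption is not yet expressed in it.
`ratio_vs_dilution` orders the gas ratio by a dilution index (δ³He,
falling back to CH₄ or ΔT) and attaches a Kendall tau with p-value;
consumption of the numerator appears as significantly positive tau.
The consumption test is this package's formalization of what field
studies usually judge qualitatively from the same plots.

## Radiotracer rates

**Dark CO₂ fixation.** rate = (DPM_sample − DPM_blank)/DPM_added ×
C_DIC × 1.05 / t, scaled µmol L⁻¹ → µmol m⁻³. Defaults follow the
shipboard protocol: 1,380 kBq ¹⁴C-bicarbonate per 40 mL bottle, DIC
2,100 µmol L⁻¹, blank = mean of formaldehyde-killed controls. The 1.05
factor compensates the kinetic isotope discrimination against ¹⁴C. The
added activity is preferably taken from the counted start-of-incubation
aliquot scaled by volume; otherwise from the nominal kBq (1 Bq =
60 DPM). The widely cited compact notation for this formula
("DPMnet×1.05×CDIC / SA×Tr×V×T") is dimensionally ambiguous — the
specific activity SA and the bottle volume cancel in the
fraction-of-added-tracer reading implemented here; SA is retained only
for QC conversions. Negative net counts clip to zero with a flag. The
reported SE propagates Poisson counting on both counts plus the
killed-control scatter.

**Methane oxidation.** f_ox = net ¹⁴C-IC / added ¹⁴C-CH₄, rate =
f_ox × [CH₄]/t, turnover time = t/f_ox (in years). Detection requires
the sample count to exceed the killed-control mean by 2× the
killed-control SD (n−1, ≥3 controls). Note a structural property of
that rule: with the SD estimated from only three controls its null
distribution is t-like with 2 degrees of freedom, and the false-
detection rate is ~11%, not the ~2.3% of a known-σ two-sigma rule —
the calibration test in the suite states the nominal ≤5% bound and
documents that the three-control protocol cannot meet it. Users who
need calibrated detection should count more killed controls (the rule
approaches nominal calibration near ten controls).

## Incubation kinetics

Serum bottles (256 mL) sealed headspace-free receive a 24.1 mL (1 mmol)
synthetic-air headspace at sampling and are shaken hard; the default
conversion therefore assumes complete transfer of the dissolved gas:
nM = ppmv·10⁻⁶ × n_headspace / V_water. A `henry` mode credits the
residual dissolved fraction at equilibrium via dimensionless solubility
constants (H₂ ≈ 0.019, CH₄ ≈ 0.034 near 20 °C, the bench temperature at
subsampling): total = headspace × (1 + H_cc·V_w/V_h). With this
geometry (V_w/V_h ≈ 9.6) the correction is ~18% for H₂ and ~33% for
CH₄ — not negligible, which is why the mode is explicit rather than a
default correction. The temperature dependence of H_cc over the narrow
bench range is below measurement precision and is not modeled.

Bottles are destructively sampled (each time point is a fresh set), so
fits treat observations as independent. The default kinetic model is
zero-order (rate = −slope of concentration vs time), matching the
volumetric units of the fixation rates; first-order (k = −slope of log
concentration) is appropriate when depletion exceeds ~50%. The verdict
is "consumed" only when the decline is significant (one-sided t,
α = 0.05). The ensemble summary counts verdicts per water type and
averages the zero-order rate over the consuming experiments — the
averaging rule is stated here because field reports rarely spell theirs
out.

## Biomass budget

cells d⁻¹ = fixation × 10⁻⁶ / quota, with a default quota of 10 fmol C
per cell (typical small chemolithoautotroph). H₂-supported fixation
applies the growth efficiency mole-for-mole (default 0.25, the upper
range for aerobic hydrogen oxidizers); an electron-balance variant
(2 e⁻ per H₂, 4 e⁻ per C, i.e. half the mole-basis yield) is provided
separately and clearly labeled. Attribution divides H₂-supported by
total fixation, capping the report at 1 with a flag. Community increase
divides the cell yield by a standing stock the caller must supply.

## Synthetic data

The generator draws every pipeline input from a `VentScenario` holding
the ground truth: endmember temperature and composition, vent power,
stratification N, H₂ consumption constant, noise model, and seed. Two
presets encode the study conditions of the two Gakkel Ridge sites the
package was built around: `polaris` (270 °C; 2.7 mM CH₄, 3.3 mM H₂;
130 MW; δ³He up to 75%; minimum dilution 9,000; k = 0.5 d⁻¹ H₂ loss)
and `aurora` (370 °C; 1.4 mM CH₄, 14 mM H₂, 6.8 mM Fe, 0.7 mM Mn;
24 MW; δ³He up to 10%; minimum dilution 45,000; conservative gases).

Design choices that matter:

* **Casts** carry a linear density gradient set by N, a flat-topped
  anomaly block with 20 m cosine ramps over the plume interval
  (turbidity +0.3 NTU, temperature +20 mK, redox −25 mV), and Gaussian
  instrument noise (2 mK, 0.02 NTU, 2 mV, 2×10⁻⁴ kg m⁻³ by default).
  Recovery tolerances in tests derive from the ramp width and grid step
  recorded in the ledger.
* **Bottles** draw dilution factors from a lognormal (default median
  10⁴, σ_log 0.5 — median 10⁵ for the aurora preset, whose minimum
  dilution is 45,000) truncated at the preset minimum by rejection.
  Plume age grows log-linearly with dilution (zero at minimum dilution,
  full range over 3 σ_log, ±0.3 d jitter) rather than being drawn
  independently: dilute plume water is old plume water, and only this
  coupling lets first-order H₂ loss appear as the observed collapse of
  H₂/CH₄ toward zero in dilute samples. An age independent of dilution
  would attenuate H₂ uniformly and be invisible to any mixing-space
  test. δ³He scales as 1/D, normalized to the preset maximum at minimum
  dilution. Concentration noise is proportional (CV 5%).
* **Incubations** follow a default campaign mirroring a realistic
  shipboard effort: stable reference and buoyant-plume waters, one
  stable non-buoyant CH₄ experiment, and six non-buoyant H₂ experiments
  of which four consume at zero-order rates (64, 25, 18, 13 nM d⁻¹ —
  ensemble mean 30), three bottles per time point, measurements emitted
  as headspace ppmv through the forward complete-transfer model so the
  conversion round-trips exactly.
* **Assays** use Poisson counting statistics on sample and killed
  counts; default DCF campaigns draw plume rates uniform on
  [5, 45] µmol C m⁻³ d⁻¹ and background rates on [0.5, 1], the ranges
  observed in Arctic plume and deep-water samples.

Randomness uses one `numpy` Generator per output table, seeded as
(scenario seed, table index), so enlarging one table never perturbs
another. Identical scenario and seed give byte-identical output, and
every generator returns a ground-truth ledger that recovery tests
compare against instead of hard-coded numbers.

**What the synthetic tests do not show.** Dilution is drawn, not
advected: there is no plume hydrodynamics, no spatial autocorrelation
along tow-yo sections, no covariance between bottle depth and dilution,
and instrument noise is uncorrelated Gaussian with constant CV. Passing
recovery tests therefore demonstrates the correctness of the inference
chain under the stated statistical model, not robustness to sensor
drift, patchy venting, or tidally advected plume filaments.

## Problem sizes and runtime

Default test and acceptance runs use 3 reference + 2 plume casts at
10 m resolution, 30 plume + 8 reference bottles, the 10-experiment
incubation campaign, a few hundred assays for recovery checks, and
1,000-replicate null Monte-Carlos for detector calibration; the whole
suite completes in seconds on one CPU. All sizes are arguments, so
larger campaigns are one call away.

## Known limitations

* Single-scalar MTT inversion only: no entrainment profiles, bent-over
  plumes in crossflow, or multi-source superposition.
* Temperature is the only conservative scalar used for dilution; no
  chlorinity/silica endmember extrapolation.
* δ³He inputs are assumed corrected for tritiugenic ³He upstream.
* No scintillation quench or counting-efficiency modeling; DPM inputs
  are taken as counter-corrected.
* No oxygen drawdown modeling in incubations (oxygen is orders of
  magnitude above the electron donors in these waters).
* The MOx 2σ detection rule is anti-conservative with few killed
  controls, as quantified above.
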