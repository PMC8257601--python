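# Methods

This note documents the models, conventions and numerical choices
behind `littertrace`, and what the synthetic generator does and does
not emulate.

## Isotope arithmetic

All isotope work is anchored on the V-PDB ¹³C/¹²C ratio, fixed at
0.0111802 (the standard literature value) and exposed through
`IsotopeStandard`. δ-notation and atom fraction interconvert through
R = R_VPDB·(1 + δ/1000), af = R/(1+R); the two functions are exact
inverses and are property-tested as such over δ ∈ [−900, 10000] ‰.

Two-pool mixing assumes the measured δ of a mixture is the
mass-weighted linear combination of the end-member δ values. Strictly,
mixing is linear in atom fraction, not δ; at the enrichment levels
involved here (end members −28 ‰ and +2129 ‰, af ≈ 0.011 and 0.034)
the δ-linear form is the standard field convention and the synthetic
generator composes mixtures with the same convention, so the analysis
inverts it exactly.

The natural-abundance control default is **−28 ‰ V-PDB**. Conventional
notation sometimes drops the sign when quoting natural abundance;
unlabeled temperate soil organic matter sits near −28 ‰, so the
negative value is the default, and it is configurable everywhere it is
used.

Mixing fractions are clamped to [0, 1]. Excursions within a tolerance
(default 0.02) are clamped silently — measurement noise routinely
pushes δ_mix slightly past an end member — while larger excursions
raise a `MixingClampWarning`.

## Respiration

Flux conversion uses the ideal-gas law with a molar volume of
24.1 ml mmol⁻¹ (21 °C, 1 atm; `molar_volume_ml_per_mmol` computes it
from scipy's constants) and 12 mg C mmol⁻¹. The default headspace
volume is 377 ml: a 475 ml jar minus the ~98 cm³ displaced by the
microcosm body; both are configurable.

Each measurement day contributes one accumulation interval (two
headspace samplings). Cumulative curves integrate the daily rates
**trapezoidally** over the sampling days, holding the first measured
rate constant back to day zero. Linear-in-rate interpolation was chosen
over linear-in-cumulative because respiration rates decay smoothly
between samplings; the alternative changes cumulative totals by less
than the trapezoid error bound tested in the suite.

Partitioning of litter-treatment intervals uses the mean δ¹³C of the
control microcosms of the same texture and day as the soil end member,
falling back to the configured constant when no controls were measured.

Priming is defined observationally, not mechanistically:
priming(t) = soil-derived cumulative CO₂-C in the litter treatment
minus total cumulative CO₂-C in the paired control, both per g bulk C
and averaged across replicates. It is identically zero when the
generator's priming multiplier is 1.

## Fraction accounting

C content is treated as organic C (no carbonate correction — intended
for carbonate-free soils). Per-g-C_bulk normalisation divides by the
bulk C of the same depth increment, not the microcosm mean, matching
the depth resolution of the fraction data. Recovery QA warns outside
90–105 % (mass) and 85–110 % (C); these are advisory thresholds, not
errors.

## PLFA

The methanol correction removes the methyl carbon added during
methanolysis by isotope mass balance; it is the exact inverse of the
forward methylation model the generator uses, and the round trip is
tested to 1e-9.

The marker map is data: the default assigns the conventional
mono-unsaturated/cyclopropylated markers to gram-negative bacteria,
iso/anteiso-branched markers to gram-positive, the polyunsaturated
C18:2ω6c/C18:3ω3c/C20:5ω3c to fungi, and C14:0, C16:0, C20:0, C15:1 to
a general bacterial pool. The gram-positive list keeps the entries
"C:17" and "C18:0" as conventionally printed even though C18:0 is
arguably a general marker; users override the whole map via TOML
rather than the package silently reinterpreting it.

"Enriched" has no universal definition, so the rule is explicit: a
fatty acid is enriched when its atom-fraction excess over the matched
control mean exceeds 3 control standard deviations, falling back to an
absolute excess of 5e-4 atom fraction when the controls provide no
spread. Both the multiplier and the fallback are parameters.

The between-group incorporation metric weights each enriched fatty
acid by concentration × atom-fraction **excess** (not raw atom
fraction), so natural-abundance ¹³C cancels; concentrations are
reported as nmol C-FA g⁻¹ soil, i.e. already per fatty-acid carbon, so
no additional chain-length factor enters. A mole-proportion weighting
is the plausible alternative; excess-mass weighting is the default
because it measures where the label physically went.

## NMR molecular mixing model

Quantification regions: alkyl −10–45, O/N-alkyl 45–110, aromatic
110–160, carboxyl 160–220 ppm. MMM regions: 0–45, 45–60, 60–95,
95–110, **110–145**, 145–165, 165–215 ppm (the aryl region lower bound
is taken as 110 so the set is contiguous and non-overlapping).
Integration is trapezoidal on the native ppm grid with linear
interpolation at region bounds (closed-lower/open-upper); descending
axes are re-sorted ascending.

The unmixing solves min ‖Ax − b‖₂ s.t. x ≥ 0, Σx = 1 via SLSQP
followed by an exact KKT refit on the active support, so targets
inside the signature simplex reach residuals ≤ 1e-10. A brute-force
grid search over the simplex serves as an independent oracle in the
tests and acceptance script.

The signature matrix itself is a **data asset**
(`data/mmm_signatures.toml`), with values in the lineage of the
terrestrial molecular-mixing-model literature (Nelson & Baldock). No
claim is made that these exact numbers match any particular published
calibration; the solver and all validation are independent of the
matrix, and users supply their own. The N:C-constrained MMM variant is
out of scope; the fit is purely spectral, and reported fractions are
fractions of spectral C intensity.

Spectra are assumed phased and baseline-corrected; a linear baseline
subtraction is available behind a flag. No spinning-sideband handling.

## NanoSIMS

Dead-time correction uses the non-paralyzable model
n_true = n/(1 − n·τ/T) with τ = 44 ns and T = 1 ms dwell, applied per
pixel per plane (per-plane correction is more faithful to the count
statistics than correcting the accumulated image; the difference is
second-order at these count rates). Saturation raises an error naming
the offending pixel.

Drift alignment maximises the integer-pixel cross-correlation of each
¹²C¹⁴N⁻ plane against the running sum of already-aligned planes; the
winning shift is applied to all species. Sub-pixel registration and
QSA correction are out of scope.

ROI ratios pool the summed counts over the ROI rather than averaging
per-pixel ratios (algebraically identical to the count-weighted pixel
mean, but unbiased at low counts); Poisson standard errors come from
error propagation, se = √(ab/(a+b)³). An ROI is called ¹³C-enriched
when its ratio exceeds natural abundance by more than k·SE (k = 3 by
default). The per-pixel ratio map masks pixels under 20 accumulated
counts by default.

## Synthetic generator

The generator emulates the target study design: 2 textures × ±litter ×
5 replicates, sampling days 2–95, three depth increments, five
fractions, the conventional marker set, and 40-plane 1 ms-dwell ion
images. Source fluxes are two-pool (fast + slow) exponentials per
source — the simplest shape producing realistic saturating
cumulatives — and priming is a multiplicative factor on basal soil
flux in litter treatments. Default magnitudes place the litter share
of respiration near 31 %, coarse-texture priming near 23 mg CO₂-C g⁻¹
C_bulk, and hyphal labeling near 3 atom % ¹³C, i.e. in the
neighbourhood of what such incubations report; these are scenario
choices, not measurements, and nothing asserts equality with any
laboratory value.

What it does *not* emulate: diffusion limitation in the headspace,
temporal autocorrelation of measurement noise, chromatographic
co-elution, NMR lineshape distortions (spinning sidebands, baseline
roll), detector QSA, or spatially structured drift within a plane.
Passing the recovery tests therefore demonstrates correctness of the
computations under the stated measurement models, not robustness to
every artefact of real instruments.

Problem sizes in the tests and the acceptance script (64 × 64 px ion
images, 200-pixel ROIs, 100–200 Monte-Carlo draws) were chosen to give
stable pass/fail statistics at interactive runtimes; all are
parameters of the respective functions.

All generators are pure functions of (config, seed) using
`numpy.random.SeedSequence` child streams, so every dataset is
byte-identical on regeneration and every noiseless dataset is exactly
invertible by the analysis — the module's core contract.

## Known limitations

- Two-source partitioning only; no Keeling plots or >2-source mixing.
- One gas-accumulation interval per measurement day.
- The respiration CLI applies a single bulk-C mass to all microcosms
  in a table; per-texture normalisation requires separate runs or the
  library API.
- Only ¹³C is supported; no ¹⁵N/¹⁸O, and no instrument-side
  calibration (IRMS linearity, electron-multiplier ageing) is modeled.
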