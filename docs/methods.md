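# Methods

This note records the models implemented in `ricegi`, the defaults and the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Hydrolysis kinetics, AUC, HI, eGI

Starch digestion curves are modelled as `C(t) = C∞(1 − e^(−kt))`. Fitting
is damped least squares (trust-region reflective) with the analytic
Jacobian. Initialisation: `C∞⁰ = 1.05·max(C)`; `k⁰` from an ordinary
regression of `ln(1 − C/C∞⁰)` on `t` through the origin over points below
the plateau. If the solver fails, or lands worse than a constant fit, a
10×10 log-spaced restart grid over `(C∞, k)` is searched and the best
restart kept; the `converged` flag records optimizer status. Bounds:
`C∞ ∈ (0, 120]` (the % scale with headroom for noisy plateaus above 100),
`k ∈ (10⁻⁶, 10]` min⁻¹. Fits are invariant to timepoint order (inputs are
sorted). An all-zero curve is rejected as degenerate.

The AUC on `[t0, tf]` (defaults 0 and 240 min, exposed as parameters) uses
the exact closed-form integral of the model. The glucose reference is
fitted with the same model and its AUC computed the same way — it is a
measured curve, not assumed to be `C∞ = 100`. `HI` is expressed on the
0–100 scale so the calibration `eGI = 39.6207 + 0.5498·HI` lands in the
familiar 68–76 range for `HI ≈ 52–66`.

Englyst fractions are taken from the fitted model at 20 and 120 min by
default (this smooths measurement noise); a raw-interpolation mode is
available, and a raw curve that decreases between 20 and 120 min floors
SDS at 0 with a warning. The hydrolysed percentage is capped at 100 before
conversion — digested starch cannot exceed the total it is expressed
against — which makes derived-mode fractions satisfy
`RDS + SDS + RS = TS` exactly even when a noisy fit plateaus slightly
above 100 %. RS is either passed through from an independent measurement
(`measured`) or derived as `TS − digested(120)` (`derived`); both modes
exist because kit-measured RS/TS and curve-derived fractions are
independent measurements that need not reconcile, and the package does not
guess a reconciliation rule. Curve values are treated as % of TS
hydrolysed; the `basis` field is a pass-through label. No free-glucose
correction is applied.

## RVA digestograms and pasting metrics

Digestograms are fitted to `μ(t) = μ∞ + (μ0 − μ∞)e^(−kt)` with `t = 0` at
enzyme addition (any pre-hold must be trimmed by the reader).
Initialisation `μ0⁰` = first reading, `μ∞⁰` = last, `k⁰ = 1`, with the
same restart policy as the hydrolysis fit. A constant trace leaves `k`
unidentifiable; the fit then returns `μ0 = μ∞ = mean` flagged
`identifiable=False` rather than an arbitrary rate. cP and mPa·s are
treated as identical.

Pasting metrics: VPEAK is the maximum viscosity within the
heating/holding window. When the trace carries a temperature channel the
default window ends at the last sample of the maximum-temperature hold, so
the cooling (setback) rise is never mistaken for the peak; without a
temperature channel the whole trace is searched. Setback is defined as
final viscosity minus VPEAK — note this differs from the trough-based
setback some RVA software reports — and may legitimately be negative.

The gelatinization-temperature detector is a clearly-labelled surrogate
for the instrument-standard procedure: it returns the temperature at which
viscosity first exceeds the pre-ramp baseline median plus a threshold
(default 5 % of the trace maximum above baseline) during the heating ramp,
linearly interpolated between samples. A trace that never responds yields
an absent value with a warning. Because the onset is detected part-way up
the viscosity rise, the surrogate carries a small positive bias relative
to the constructed onset temperature; it is monotone in the true onset,
which is what the correlation analyses need.

## Cooking parameters and classification

`WUp = 100(cooked − uncooked)/uncooked` (mass), `VER = cooked/uncooked`
(volume), `SL = 100(W1 − W2)/uncooked mass`. The SL formula is implemented
verbatim — per 50 mL aliquot of cooking water — with an explicit opt-in
mode scaling by `total_water/aliquot_volume`; whether published SL values
used that scaling cannot generally be determined, so fidelity comes first
and the utility mode is opt-in.

The four biometric trade rules (Long A: length > 6.0 mm,
2 < ratio < 3; Long B: length > 6.0, ratio ≥ 3; Medium: 5.2 < length <
6.0, ratio < 3; Short: length ≤ 5.2, ratio < 2) are applied with strict
inequalities exactly as printed. They do not tile biometry space: boundary
grains (length exactly 6.0 mm, ratio exactly 2) and the gap at
length ≤ 5.2 with ratio ≥ 2 return `unclassified` rather than a guessed
label. Aromatic types are commercial metadata, never inferred.

## Statistics

Group comparison: per-variable one-way ANOVA plus all-pairs Tukey–Kramer
HSD (studentized-range based, valid for the unbalanced 11/3/3/2/2 design;
`scipy.stats.tukey_hsd` supplies the pairwise p-values). Groups with one
observation are excluded from testing but still summarised. Letters come
from the insert-and-absorb compact-letter-display algorithm with letters
ordered by descending group mean; two groups share a letter exactly when
their pairwise comparison is not significant at α (default 0.05). Zero
pooled variance merges all groups under one letter with a warning.

Correlations: pairwise-complete Pearson `r` with the exact two-sided
t-transform p-value on `n − 2` degrees of freedom; the significance mask
keeps `p ≤ α` and is display-only (the underlying matrix is untouched;
display rounding to 1 decimal is presentation-only). No family-wise
correction is applied by default — matching the per-pair 5 % screen such
studies report — and a Bonferroni option is exposed. Constant columns
yield missing correlations.

PCA: variables are centred and, by default, scaled to unit variance
(standardization is the package's assumption for mixed-unit tables — cP
next to % — and can be disabled); decomposition by SVD with each loading
column sign-fixed so its largest-magnitude entry is positive. Variance
fractions are reported over all components and sum to 1;
`scores × loadingsᵀ` reconstructs the standardized data to machine
precision. Missing rows are dropped listwise with a log message; a
zero-variance column under standardization is an error naming the column.

## The synthetic panel generator

The generator emulates the data structure of a 22-variety, six-type
commercial panel (Long A 11, Short grain 3, Long B 3, Medium grain 2,
Basmati 2, European Aromatic 1).

**Variety table.** A Gaussian copula: a multivariate-normal latent draw
with a target 16×16 correlation matrix, shifted/scaled per variable to
per-type means and pooled SDs chosen once to sit in the ranges published
for such panels (eGI ≈ 68–76, RS highest in Long B and Basmati, Tg ≈
64–73 °C, SB spanning ≈ 260–2320 cP, …). The default target correlation
is built from an explicit three-factor model — a digestibility factor
(eGI, RDS, RS, Tg, SB), a composition factor (FIBER, PRTD, TS, WUp, SL)
and a retrogradation/expansion factor (AMYL, VPEAK, SB, VER) — whose
loadings reproduce the strong published pairwise coefficients exactly
(r(RS, eGI) = −0.90, r(Tg, eGI) = −0.90, r(SB, eGI) = −0.70,
r(RDS, eGI) = +0.90, r(FIBER, PRTD) = +0.70, r(PRTD, SL) = −0.60, …) and
is positive semi-definite by construction, so no repair step distorts the
targets. User-supplied matrices (e.g. assembled from coefficients rounded
to 0.1, which are often slightly indefinite) are repaired by clipping
negative eigenvalues to 10⁻⁸ and renormalising the diagonal, with a
warning. Latent draws are deliberately not truncated at physical bounds —
a variable with a mean near zero (RS in high-GI types) can dip slightly
negative — because truncation would bias the correlation structure the
generator contracts to deliver.

**Curves.** Per-type default kinetics (C∞, k) were derived by inverting
the AUC → HI → eGI chain from the per-type eGI means against the glucose
reference (C∞ = 100, k = 0.35 min⁻¹, higher in both parameters than every
variety): Long A (76.1, 0.023), Short grain (77.1, 0.023), Long B
(66.2, 0.019), Medium grain (78.2, 0.025), Basmati (64.5, 0.020),
European Aromatic (75.8, 0.023). When a variety table is supplied,
per-variety C∞ is solved from the table's eGI at the type's k, so
curve-derived eGI carries the table's correlation structure through the
pipeline. Noise is additive Gaussian (default sd 1.5 percentage points, a
realistic assay repeatability; the underlying study reports no error
model) truncated below at 0 and applied at t > 0 only — the time-zero
reading is definitionally zero hydrolysis. Default timepoints
0/20/60/120/180/240 min include 20 and 120 so Englyst fractions are
computable from the curve. A replicates parameter (default 1) exists
because replicate counts for the kinetic assays are not published.

**Raw measurements.** Cooking weights/volumes invert WUp/VER/SL from 12 g
uncooked rice and 120 g water; biometry uses type-typical grain
dimensions plus 0.08/0.05 mm measurement noise. Digestograms are exact
first-order decays (μ0 ≈ 1900 cP, μ∞ ≈ 200 cP, k from the table's k_RVA)
sampled at 4 s over 5 min plus Gaussian noise (default sd 15 cP). Pasting
traces follow a heat–hold–cool program (50 °C 1 min, +10 °C/min to 95 °C,
hold 2.5 min, −10 °C/min to 50 °C) with a piecewise raised-cosine
viscosity profile: onset where the ramp crosses the variety's Tg, rise to
VPEAK, shear-thinning decay to a trough, cooling rise to VPEAK + SB.
Pasting traces are generated noiseless because their construction
contract — exactly one interior viscosity maximum — is a structural
property additive noise would violate.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: instrument artefacts (rotation-speed changes,
thermal lag), within-variety biological replication structure, basis
inconsistencies between kit-measured and curve-derived starch fractions,
non-Gaussian measurement error, and any bran-chemistry effects on
digestibility. Tests against the generator demonstrate correctness of the
computational chain under its stated statistical assumptions, not field
validity of those assumptions.

## Problem sizes and reproducibility

The shipped experiments use: 100 noiseless and 200 noisy replicates for
kinetic recovery, 1000 draws for the AUC/quadrature identity, 200 noisy
digestograms, 50 random instances plus 500 null replicates for the
Tukey-letter checks, a 200-variety single-type panel for the correlation
round trip, and the default 22-variety panel for the end-to-end pipeline
— sizes at which Monte-Carlo error is far below the tolerances being
checked while a full run stays interactive. All generators are
deterministic in (config, seed), each output family on an independent RNG
stream, so outputs do not depend on call order; pipeline reruns with the
same seed are numerically identical, and CSV outputs are written at 6
significant digits with fixed column order.

## Known limitations

- The Tg surrogate is not the instrument-standard measurement; absolute
  values carry a small positive bias.
- The eGI calibration is applied as a fixed linear map; no uncertainty is
  propagated from the curve fit into eGI.
- The compact letter display is a summary of pairwise tests; with heavily
  unbalanced designs, non-transitive significance patterns can make
  letters conservative (more shared letters than a transitive pattern
  would give).
- Derived-mode RS inherits any plateau misfit of the curve model;
  measured-mode RS is preferred when kit measurements exist.
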