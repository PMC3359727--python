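# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic-data generators emulate, and the known
limitations.

## Sequence features

Monomer molecular weight is the sum of average (not monoisotopic) residue
masses plus one water (18.0153 Da), using Biopython's amino-acid weight
table; average masses match protein-chemistry convention for purified
samples. An `X` residue contributes the mean of the twenty standard residue
masses. GRAVY is the unwindowed mean of Kyte–Doolittle hydropathy values
(`X` excluded). For multi-protein samples the predictor uses the maximum MW
and maximum disorder stretch over the sample's sequences.

Disorder is an injection point. Per-residue boolean calls from any external
predictor can be supplied (two-column CSV: position, call or probability
with a 0.5 cutoff) and always take precedence. Without them a fallback
heuristic is used: per-residue score `0.5 + 0.5·(charge − KD/4.5)` smoothed
over a 15-residue window and thresholded at 0.5. It captures the
charged/low-hydropathy signature of disorder but is *not* a trained
predictor; outputs are labelled `fallback-heuristic` so downstream users can
tell which disorder source produced `l_dis`. The longest contiguous run of
disordered calls, `l_dis`, is the predictor feature.

## DSF (thermofluor)

Model: `F(T) = F₀ + Σⱼ ΔFⱼ / (1 + exp((Tmⱼ − T)/sⱼ))` with a single
additive baseline `F₀` (sloping baselines are a known limitation). Input
temperatures with a maximum below 150 are treated as Celsius and converted
to Kelvin. The fit region runs from the first point to the global maximum of
the 3-point-moving-average-smoothed fluorescence (ties break to the latest
index, so monotone or flat curves keep the full range); beyond that maximum
dye-aggregate dissociation makes the signal uninformative.

Fitting is damped least squares (scipy `least_squares`, TRF with bounds
`s ∈ [0.05, 50] K`, Tm within the data range ± 20 K). Initialization seeds
Tm at the k largest local maxima of the smoothed derivative and `s` at 2 K;
up to 5 restarts jitter the seeds with a seeded RNG, so fits are
reproducible. Derived per transition: `max_slope = ΔF/(4s)` and
`FWHM = 2 ln(3+2√2)·s ≈ 3.5255·s`, both exact identities of the fitted
parameters. The steepest transition (largest `max_slope`) is the major one
by default, with a persistent user override.

The predictor value is `r_dsf = F(303.15 K)/F(Tm_major)` evaluated from the
fitted model. The direction (30 °C fluorescence in the numerator, so
already-unfolded/dye-binding samples score high) is this package's stated
convention; any imported tree thresholds must be expressed against it.
Transition-count selection (`--k auto`) picks the smallest k whose BIC is
not improved by more than 10 at k+1 (Gaussian-error BIC,
`n·ln(RSS/n) + p·ln n`).

## SEC

The run log supplies flow rate (mL/min), fraction size (mL) and collection
start (min); elution time maps to a continuous fraction coordinate
`(t − start)·flow/size + 1`, with fraction boundaries half-open in volume,
1-based indices, and pre-collection points assigned fraction 0.

The trace is fitted with a Gaussian mixture
`A(f) = Σ hᵢ exp(−(f−cᵢ)²/2wᵢ²)` by bounded least squares; seeds come from
local maxima of a 5-point-smoothed trace above a noise floor of
median + 3×MAD of the *raw* trace (the raw MAD is used because smoothing
shrinks the noise spread and would put baseline wiggles above a floor
computed on the smoothed data). The component count defaults to the number
of seed peaks.

Pooled purity integrates each component analytically (erf) over the pool
window in continuous fraction coordinates `[first, last]` and reports the
largest component share as a percent; the "main" species is the component
with the largest in-pool integral — what was actually pooled — not the
globally tallest peak. A pool window with no mixture mass yields a missing
value.

The predictor value is `r_sec = RSS₁/TSS` of the best single-Gaussian fit
(1 − R² form, clamped to [0, 1]); normalizing by the total sum of squares
makes it dimensionless and comparable across instruments and scales.
Constant traces have undefined `r_sec` (missing).

## DLS

Starting point is a vendor-style peak table (Rh, Pd, %Pd, %intensity,
%mass); autocorrelation deconvolution is out of scope. The major peak is the
highest-intensity peak with Rh in 2–10 nm (the globular-protein window;
smaller populations are buffer components, larger are aggregates), ties
toward smaller Rh; if no peak qualifies, the global maximum is used with a
warning flag. Particle MW uses the widely used globular calibration
`MW[kDa] = (1.68·Rh[nm])^2.3398`; the constants are configurable since
vendor calibrations differ. Derived values: oligomer ratio
`n_olig = MW(Rh)/MW_monomer` (≈1 monomer, ≈2 dimer);
`p_maj = I_major / Σ{Iⱼ : Rhⱼ ≥ Rh_major}` (smaller particles excluded);
and a display-only ordinal DLS score (4 = single monodisperse peak,
%Pd < 15; 3 = single polydisperse peak; 2 = multiple peaks, major ≥ 50%
intensity; 1 = otherwise — rubric shipped as editable config). The default
predictor feature from DLS is `p_maj`; `n_olig` is computed and can be
swapped in for user-trained trees.

## Gel-based scores

Yield: visual 0–5 scale with level 5 ("extremely high") anchored at
≈100 mg per liter of culture (intermediate anchors 0/5/15/35/65/100 mg/L
are this package's interpolation); the predictor uses the visual score when
recorded, else mg/L, and the returned value is tagged with its kind.

Limited proteolysis: each protease digest is scored 1 (unstable) to
5 (extremely stable) from the major band's MW change and intensity retention
at 1 h and 24 h. Rubric: 5 needs ≤5% MW change and ≥90% retention at 24 h;
4 = intact (≥90%) at 1 h and ≥50% at 24 h; 3 = intact at 1 h but <50% at
24 h (or no 24 h observation — the conservative call when the later
timepoint is absent); 2 = 10–90% at 1 h; 1 = <10% at 1 h. The interior
thresholds interpolate between the scale's defined endpoints and are
shipped as config. Sample stability is the unrounded mean over proteases.
The SDS purity score and Lp stability are stored and serialized but do not
enter the default feature vector (the historical training data lacked
poor-gel outcomes, and stable-protein cases were too few to be significant);
a flag can add Lp for user-trained trees.

## Regression tree

CART with variance reduction: greedy binary splits maximizing the decrease
in the sum of squared score deviations, candidate thresholds at midpoints
between adjacent observed values of each feature, stopping at min leaf size
(default 5), max depth (default 5) or zero gain. Leaves store the exact mean
and the full 0–6 outcome histogram of routed training samples; an optional
test cohort is routed alongside to populate test histograms. Missing values
route to the child holding more training samples (majority-child rule —
chosen over surrogate splits as the simplest deterministic contract), both
in training and at prediction time; the imputation is flagged on the
decision path. Equal child means mark a path step neutral rather than
favorable/unfavorable. Monomer MW is the one mandatory feature.

Interpretation bands over the leaf mean (config): < 1 "not likely to form
crystals"; ≥ 4.5 "likely to form crystals with diffraction of 2.8 Å or
better"; graded bands between. Suggestions map each unfavorable path split
to feature-specific advice (disorder truncation, expression/purification
changes for yield or SEC, construct-boundary changes for MW); a top-category
sample flagged as having no crystals yet receives screening-resource advice
instead.

No reference tree ships with the package: published trees of this kind do
not print their split thresholds, so the package provides the trainer plus a
JSON tree-definition format in which any external tree can be encoded
verbatim.

## Synthetic data

The generators define the study conditions used throughout the tests. DSF:
293–363 K at 0.5 K steps, baseline 200, one transition (Tm 323 K, s 1.5 K,
ΔF 1000) by default, 1% multiplicative Gaussian noise (typical plate-reader
level), optional linear decay starting 3s past the last Tm. SEC: 40
fractions at 10 points/fraction, mAU-scale Gaussian components, additive
noise as a fraction of the tallest peak. DLS: peak tables with intensity
percentages summing to 100 and a log-spaced intensity histogram. Cohorts:
mw lognormal (median 35 kDa, σ_log 0.5), l_dis geometric-like (mean ≈ 33,
capped at 300), r_dsf/r_sec/p_maj beta-shaped in their natural ranges,
ordinal 0–5 yields, and scores from a planted single-split rule
(default `l_dis ≤ 40 → 5 else 0`) plus clipped Gaussian noise (σ = 0.5),
rounded to 0–6. Problem sizes in the test suite (20-seed repetitions,
n = 100 cohorts, ≤ 4-peak DLS enumerations) were chosen as the smallest
sizes at which the statistical checks are stable.

What the generators do **not** emulate: sloping DSF baselines and
temperature-dependent dye quantum yield; asymmetric/tailing SEC peaks and
column non-idealities; DLS autocorrelation noise and regularization
artifacts; correlated feature structure in cohorts. Passing tests therefore
demonstrate correct recovery under idealized noise, not robustness to every
instrument artifact.

## Numerical choices and degenerate inputs

Numbers in the standardized XML carry 12 significant digits; round-trips are
exact at that precision. Fits reject underdetermined configurations
(DSF: region < 4k+2 points; SEC: < 3k+2). Flat DSF curves keep the full fit
region (latest-index argmax tie-break); constant SEC traces and empty pool
windows report missing rather than 0. Empty result selections aggregate to a
missing marker, never zero. All RNG use (restart jitter, generators) is
seeded explicitly.

## Limitations

- The DSF ratio direction, the SEC residual normalization, the DLS
  radius→MW constants and the DLS score rubric are package conventions
  (configurable); thresholds imported from elsewhere must be restated
  against them.
- Single additive DSF baseline; no sloping-baseline correction.
- The fallback disorder heuristic is not a substitute for a trained
  disorder predictor and is clearly labelled in outputs.
- No cross-validation or model-selection machinery for trees; the trainer
  reproduces the mechanism, not any particular published fit.
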