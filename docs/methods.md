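# Methods

This note documents the models, numerical choices and known limitations of
`lamap`. It describes what the code computes; every number quoted here is
produced by the test suite or the acceptance script, not asserted from
memory.

## Acquisition model and pixel grid

A run is an ordered set of ablation lines; each line is an ordered sequence
of acquisition cycles carrying one raw intensity per m/z channel (28 channels
by default, including the ¹³C reference and two isotopes per element where
available: Fe56/Fe57, Cu63/Cu65, Zn64/Zn66). The rasterizer maps cycle c of
line r to pixel (r, c). Pixel pitch along track is scan speed × cycle time —
stored unrounded (70 μm s⁻¹ × 0.341 s = 23.87 μm) and rounded to whole μm
only for display (24 μm) — and the between-line pitch is the line spacing
(ablation spot 60 μm + residual 30 μm = 90 μm). The anisotropic grid is
preserved; there is no interpolation to square pixels, no smoothing and no
between-section registration. Ragged lines are right-padded with NaN
sentinels; every downstream mean excludes sentinels.

## Forward instrument model (synthetic data)

The simulator exists so the full chain can be validated without instrument
data. Its structure is the minimal model the analysis assumes, which makes
the chain exactly invertible in the noiseless limit:

1. **Linear response.** Expected counts = sensitivity × concentration +
   background, per channel. Default sensitivities and backgrounds are of
   realistic quadrupole magnitude (e.g. a high Fe56 background standing in
   for the ArO⁺ interference, a low-sensitivity Fe57 channel).
2. **Spot smearing.** The ablation spot averages the concentration profile
   over 60 μm of travel. Implemented as an exact moving average of the
   piecewise-constant pixel profile (cumulative-integral form), renormalized
   to the covered width at the scan-domain edges. With 90 μm line spacing and
   a 60 μm spot there is no between-line overlap, so smearing is purely
   one-dimensional along the travel direction.
3. **Poisson counting noise** (optional), applied to expected counts.
4. **Multiplicative drift**, linear in line index from 1.0 at the
   standard-adjacent end to a per-run endpoint factor. Applied after noise.
5. **¹³C channel** emitting a tissue level over labeled pixels and a glass
   level elsewhere (defaults 50 000 / 2 000 intensity units), with the same
   smearing, noise and drift treatment — a slice-thickness surrogate.

Standards are homogeneous blocks at known concentrations simulated with the
same response and noise; they are acquired as compact blocks at the drift
anchor, so their drift factor is 1. The default series is a blank plus two
levels spanning each element's tissue range (e.g. Cu 0/10/80 μg g⁻¹,
Mn 0/0.3/1.2 μg g⁻¹), two lines × 60 cycles per level.

**Phantom and cohort.** The default phantom is a scaled-down labeled section:
48 lines × 100 cycles (≈ 4.3 × 2.4 mm) containing all 20 reference regions
(cortex, corpus callosum, three cerebellar compartments, both colliculi,
three periventricular regions, ten hippocampal layers) as non-overlapping
rectangles separated by ≥ 95 μm glass gaps so the spot never smears across
region boundaries. The problem size is a deliberate choice: regions are still
≥ 3 spot diameters wide (interior-pixel recovery is exact), while a full
17-animal cohort simulates and analyzes in ~1–2 s, making replicate studies
cheap. Per-animal regional truths are drawn independently per (animal,
region, element) from normal distributions with the reference group means ±
SD, truncated at zero by clipping (the smallest mean/SD ratio in the table is
≈ 3.9σ from zero, so clipping is negligible; no covariance between regions is
modeled because only marginal mean ± SD are available). Group sizes default
to 8 control vs 9 disease-model animals. Both hemispheres of an animal share
one truth draw but are simulated as independent runs with independent seeds,
standards, noise and drift, mirroring the acquisition protocol. The three
periventricular regions are parameterized for Cu only in the reference table;
the simulator fills their Fe/Zn/Mn cells with the entire-section values so
every region × element is defined.

All randomness flows from one master seed through
`numpy.random.SeedSequence`; identical seeds give bit-identical scan sets.

## Drift estimation and correction

The per-line level of a reference channel (default: ¹³C; the choice of
reference signal is a documented package decision, not an instrument
constraint) is the median over tissue pixels — robust against region edges —
and is regressed linearly on line index. Correction factors are the fitted
line normalized to its value at line 0; the endpoint factor is
fitted(last)/fitted(first). Correction is opt-in per run: in `auto` mode it
is applied only when the endpoint factor leaves a ±2% tolerance around 1
(the model is then flagged "necessary"). Estimation needs ≥ 3 lines with
usable signal. On noiseless simulated runs the endpoint factor is recovered
to floating precision; under Poisson noise with 100 lines it is recovered
within 0.05 (seeded test).

## ¹³C normalization

Optional, off by default for quantitative output: the numeric results are
produced from non-normalized data, matching the convention that
normalization leaves group averages unchanged while adding scatter (a seeded
test verifies group-mean agreement within one standard error with
normalization on vs off, under 8% per-section thickness variation). When
enabled, the average net ¹³C level is the separation of the tissue and glass
modes of the carbon histogram: 256 bins, split at the Otsu threshold, each
mode being the most populated bin on its side, contributing the mean of its
member pixels; metal channels are divided by the net level. Standards, which
contain no glass, are normalized by their block-mean ¹³C; the glass carbon
baseline (4% of the tissue level by default) therefore introduces a small
systematic scale offset in the normalized pathway, bounded by the
glass-to-tissue carbon ratio. A unimodal histogram (no tissue/glass
separation) is a hard error, as is a non-positive net level.

## Calibration

Slope and intercept per channel by ordinary least squares of per-level mean
counts on known concentrations (≥ 2 distinct levels required; a negative
fitted slope is rejected as corrupt standards). The background used for
inversion is the fitted intercept when the series includes a blank, else the
sample's own glass-ROI mean. Each hemisphere run is calibrated strictly
against its own standard series; no drift transfer between sample and
standard runs is modeled. Negative concentrations are clamped to zero and
the clamp count is logged, never silent. Isotope pairs are calibrated
independently and compared in a validation report — never averaged. The
historical 8-bit gray pathway implements
(max − min)(gray − background_gray)/(255 · slope) with gray values defined as
the affine 8-bit quantization of raw counts (the dimensionally consistent
reading, given the 255 divisor); it agrees with the raw-count pathway within
(max − min)/(510 · slope) per pixel, verified on randomized images.

## Quantification

Region means are arithmetic means over non-sentinel pixels carrying the
region label; region SD is the sample SD (ddof = 1) across pixels. "Entire
section" is the union of all non-glass labels; periventricular ROIs include
the periventricular tissue as drawn. The per-animal value is the unweighted
mean of the two hemisphere means; an animal with a single measured
hemisphere contributes that value with a logged warning rather than
silently shrinking the group. Readout satisfies mass conservation (the
pixel-weighted sum over a partition equals the whole-section sum) and is
invariant under label renumbering.

## Statistics

Welch's heteroscedastic two-sample t-test with Welch–Satterthwaite degrees
of freedom and two-sided p-values throughout (identical groups give t = 0,
p = 1, which fixes the sidedness convention). Zero variance in both groups
with equal means returns p = 1 by convention. Percent change is
100·(x̄_case − x̄_ctrl)/x̄_ctrl, rounded half-away-from-zero to integer percent
for reporting; fold factors (control/case for decreases, case/control for
increases) round to one decimal; unrounded values are stored, so reported
percentages can differ by a few points from what the rounded printed means
would give. The classical Bonferroni threshold is α/(regions × elements) —
0.05/84 = 0.000595…, displayed to one significant figure as 0.0006 — over
the default family of 21 regions (20 drawn + entire section) × 4 elements,
configurable. Two Holm step-down variants are provided and the active mode
is recorded in the output: `standard` compares the i-th smallest p to
α/(m − i + 1); `literal` uses thresholds α/1, α/2, α/3… down the sorted
list, i.e. the face-value reading of the "first region at 0.05, second at
0.05/2, …" description, which inverts the standard ordering. Neither is
silently substituted for the other. Standard Holm provably rejects a
superset of the Bonferroni rejections; a 1 000-p-set randomized test
exercises this. p-values are stored at full precision and printed in
scientific notation below 10⁻⁵. In the formatted report, percent change is
shown only for rows with p ≤ 0.05 (blank cells read as "not significant" —
a documented convention, since the reference layout does not state it).

## Validation strategy and what it shows

* **Exact inversion (noiseless).** With noise off and drift 1, simulate →
  rasterize → calibrate recovers every region's true concentration to
  floating precision on interior pixels (pixels whose spot window stays
  inside the region). Edge pixels are blurred by the spot; for the default
  region sizes this biases full-region means by well under 1% (measured
  ≈ −0.8% for cortex).
* **Stochastic recovery.** Under Poisson noise and drift 1.2–1.3, a seeded
  8-vs-9 cohort recovers the control cortical Cu mean within sampling error
  (per-animal pipeline error SD ≈ 0.01 μg g⁻¹, far below the biological SD
  0.7), and cortex Cu clears the classical Bonferroni threshold in the large
  majority of replicate cohorts (measured 26/30 during development; the
  acceptance suite asserts ≥ 70/100).
* **Oracle equivalence.** Welch p-values are compared against a 10⁵-draw
  permutation oracle. The comparison is aggregate (mean signed difference
  consistent with zero at 3 SE) plus a per-pair bound
  |Δp| ≤ max(0.25 · p, 0.02), because the systematic gap between the t
  reference distribution and the conditional permutation distribution at
  n ≤ 10 (order 0.01) exceeds the Monte-Carlo error of 10⁵ draws and does
  not shrink with more draws; a per-pair Monte-Carlo-error criterion is not
  attainable at these sample sizes.

Passing these tests shows the chain is self-consistent and unbiased under
the stated forward model. It does not validate what the model omits:
ablation crater physics, aerosol transport and washout tails, detector dead
time, spectral interferences beyond a constant background, anatomically
realistic region shapes, or inter-regional concentration correlations.
Real-data group averages also inherit manual ROI delineation variability,
which the phantom's exact labels cannot represent.

## Reproducibility

`analyze_cohort` and the staged CLI pipeline derive every per-run seed from
one master seed; rerunning a config reproduces all numeric artifacts
bit-identically (checksum-verified in the test suite). The staged run
directory preserves scan-line tables, the truth table, the ROI label map,
per-run calibration curves, concentration TIFFs, tidy measurement tables,
the cohort report and a JSON manifest of the configuration and package
version.
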