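# Methods

## Problem and measurement model

The pipeline decides, per excised lymph node, whether its cut surface
carries tumor-accumulated PpIX. A node is measured as a small stack of
band-pass images: under 405-nm excitation the 600/14, 632/22 and 650/13-nm
bands (differential acquisition), and under 435-nm excitation the 632/22 and
680/22-nm bands before and after a 405-nm irradiation dose (ratio
acquisition). All intensities are arbitrary units; nothing downstream
depends on their absolute scale (the differential score is linear in it, the
ratio score invariant to it). Acquisition exposures are treated as
delivering negligible photoconversion fluence; only the dedicated
irradiation step converts.

## Emission and rendering model

Each fluorophore emits a sum of Gaussian peaks scaled by a per-excitation
efficiency. Defaults: PpIX 635 nm (σ 10) with a 0.15-amplitude 705-nm
shoulder, efficiency 1.0 at 405 nm and 0.6 at 435 nm (Soret-band falloff);
PPp 675 nm (σ 12); FAD 520 nm (σ 35); collagen 490 nm (σ 40). Peak
positions are the published spectral facts; widths, amplitudes and
efficiencies are free parameters exposed in the config. Filters are ideal
rectangles of width FWHM centered at CW, integrated by 0.5-nm midpoint
quadrature. A pixel renders as Σ_f concentration_f × (band integral of
fluorophore f), plus optional noise with variance `shot_gain·signal +
read_sigma²` (defaults 0.005 and 0.005 a.u.), clipped at zero, stored
float32. Zero-noise runs are a configuration (`NoiseParams(0, 0)`), not a
special code path.

Photoconversion is first order in fluence F: PpIX ← PpIX·e^(−kF),
PPp ← PPp + η·PpIX₀·(1 − e^(−kF)). Defaults k = ln 2 per J/cm² (so the
standard 2 J/cm² dose converts 75 %) and η = 0.8, both free; with η = 1 the
PpIX + PPp total is exactly conserved, which the tests exploit.

## Operators

**Differential.** Baseline = linear interpolation of the 600- and 650-band
intensities evaluated at 632 nm — the measurement band's center rather than
the 635-nm PpIX peak, because the subtraction must match the band actually
measured (under the linear model the distinction is immaterial). Negative
residuals are clipped to zero. Raw band intensities are used despite the
unequal FWHMs (14/22/13 nm); a divide-by-FWHM switch exists but is off by
default. Note the baseline over-predicts for any *convex decreasing*
autofluorescence tail, so autofluorescence can only depress this score,
never inflate it.

**Ratio.** The "675-nm" measurement uses the 680/22 filter — the only band
in the filter set covering the PPp peak. The per-pixel ratio is
I680 / max(I632, ε) with ε defaulting to 10⁻³ × the denominator image's
99th-percentile intensity (configurable absolute override); the score map is
the *increment* (post − pre), not a quotient of ratios. The node mask is
eroded by a configurable margin (default 0.2 mm = 10 px; small but larger
than the smoothing kernel) before taking statistics, because node edges are
unreliable (edge light concentration, sample shrinkage during the
tens-of-seconds irradiation). Shrinkage itself is *not* modeled or
registered; the simulator does not shrink phantoms — a documented
limitation.

**Scoring.** Both node scores are the maximum of the map over the (eroded)
mask, after an optional 3×3 median filter (default on) that keeps the
maximum statistic robust to single-pixel noise. Ratio scores may be slightly
negative on PpIX-free noisy nodes and are reported as-is; differential
scores are non-negative by construction.

## Diagnostics

Mann–Whitney U uses midranks; the two-sided p-value is by exact enumeration
of group assignments when both groups have ≤ 8 observations (correct under
ties), otherwise the normal approximation with tie-corrected variance and
continuity correction. The ROC enumerates distinct scores with the rule
score ≥ threshold ⇒ positive; the trapezoid AUC then equals the
tie-adjusted U/(n₁n₂) exactly, which the tests assert against an
independent pairwise-count oracle. The cutoff maximizes Youden's J
(ties broken toward higher specificity, then higher threshold); the
returned value is the midpoint between the selected score and the next
lower distinct score, so it classifies identically but sits away from
measured values. A closest-to-(0,1) rule is available behind a flag. The
calibration rule is a design choice — the original study reports only "the
calculated cutoff value" — as is the percentile stratified bootstrap used
for the AUC confidence interval (the study's CI method is unstated; the
bootstrap is plumbing, not a validated reproduction). Percentages are
rounded half-up to one decimal, matching the published formatting;
calibrate-on-the-full-cohort / evaluate-on-a-subset is a first-class
pipeline mode (`eval_fraction`, `eval_node_ids`).

## Synthetic cohort: what it emulates and what it does not

Defaults mirror the reference study design: 323 nodes at prevalence 41/323,
6/41 of positives micro-metastatic (< 2 mm), one cut-surface image stack
per node, pixel size 0.02 mm, node diameters 3–12 mm (elliptical masks,
disc lesions). Non-metastatic nodes carry no diffuse PpIX; nonspecific PpIX
enters only through inflammatory foci in a configurable fraction (default
0.2) of negatives. Intensity levels are log-normal per node: macro lesions
median 1.0 (σ_log 0.6), micro 0.25 (0.6) — micros are systematically
fainter, the dominant false-negative source — inflammation 0.18 (0.7), FAD
and collagen 3.0 (0.4) each with a ±10 % smooth spatial texture. The
autofluorescence medians were fixed by closed-form arithmetic on the band
coefficients: high enough that the 600-nm band is autofluorescence-dominated
(the premise of baseline estimation) and that the ratio denominator is
meaningfully diluted, low enough that micro and inflammatory residuals stay
detectable.

The generator does **not** model: depth/scattering or any 3-D optics,
sample shrinkage or pre/post misregistration, lymphoid-follicle structures,
spatially varying illumination, or absolute radiometric calibration between
the two excitation wavelengths (units are arbitrary but consistent within a
cohort). Passing tests therefore demonstrate correctness of the operators,
scoring and calibration chain under the stated forward model — not clinical
performance.

## Analytic operating point and the recovery experiment

`expected_operating_point` draws node intensity levels directly from the
configured distributions and evaluates the *noise-free lesion-peak* score in
closed form from the same band coefficients — no images, smoothing or pixel
geometry — giving the large-n sensitivity/specificity either at the Youden
optimum or at a supplied threshold. Two design points about the recovery
test that compares the image pipeline against it:

- The Youden objective of these overlapping log-normal mixtures has a broad
  plateau; its argmax is not statistically identifiable from a 400-node
  cohort. The comparison therefore calibrates Youden on the cohort and
  compares achieved vs analytic frequencies *at that cutoff*, which is
  always identifiable.
- The recovery cohort is balanced (prevalence 0.5, sharper binomial error
  on sensitivity) and noise- and texture-free, because the analytic model
  deliberately excludes pixel noise: with noise on, the max-over-pixels
  score carries a positive extreme-value bias (several percentage points of
  sensitivity at fixed cutoff) that is a property of noisy images, not of
  the chain under test. All other tests and the headline synthetic run keep
  default noise.

Similarly, the cross-method rank-concordance property (Spearman > 0.8) is
asserted on a noiseless cohort: with noise, the many clean negative nodes
have noise-floor scores whose relative ranks are uninformative jitter,
while the claim under test is that the two methods order the signal-bearing
nodes the same way.

## Numerical choices and degenerate inputs

Images are float32 (camera bit depth is a free choice); "exact" operator
identities hold to float32 precision. Mask erosion uses an L2 disc of
radius ⌈margin/pixel_size⌉ px and raises if the result is empty (node too
small to analyze). Deterministic cohorts come from `SeedSequence.spawn`
(one child stream per node); identical seeds give bit-identical cohorts and
byte-identical sidecar JSON. Class counts use half-up rounding
(`round(prevalence·n)` etc.) so small cohorts are exactly reproducible.
Single-class score tables, empty Mann–Whitney groups and empty metric
denominators raise typed errors (`SingleClassError`, `DataError`,
`UndefinedMetricError`); the CLI maps validation, I/O and data errors to
exit codes 2, 3 and 4.

## Problem sizes

The test suite uses cohorts of 4–60 nodes for unit and property checks and
one 400-node noiseless cohort for the recovery experiment; the acceptance
script runs two 400-node cohorts plus a 4×10⁵-draw analytic model, about a
minute on one CPU. A 400-node cohort is streamed node by node
(`iter_cohort`), so peak memory stays at a single node's image stack.
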