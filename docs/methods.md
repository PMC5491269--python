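# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Coordinate and angle conventions

Images use pixel centers with the origin at the top-left, x rightward and
y downward; an orientation θ means the axis points along (cos θ, sin θ) in
those coordinates. All orientations are **axial**: θ and θ+180° name the
same fiber axis, so angles live on [0°, 180°) and are analysed by doubling
(θ → 2θ) onto the full circle, the standard device for axial statistics.
The symmetric distance between two axes is min(|Δ|, 180−|Δ|) ∈ [0°, 90°].

Epidermis-relative bundle angles default to the half-circle [0°, 180°)
(orientation minus the epidermis tangent, mod 180). This preserves
bimodality — a 45°/135° basket-weave keeps two distinct peaks — and is the
form consumed by the two-peak decomposition. The folded symmetric
difference in [0°, 90°] (`fold=True`) is available where only "how far from
parallel" matters; folding would merge a symmetric two-peak pattern into
one and must not feed the mixture fit.

The angle reference defaults to the **global** length-weighted axial mean
tangent of the epidermis polyline; a **local** option uses the tangent at
the polyline vertex nearest each bundle. On the near-straight synthetic
epidermis the two agree to well under a degree; on strongly curved real
boundaries they can differ, and neither is asserted to be the "right"
reading of angles measured "relative to the epidermis" — both are exposed.

## Slide model and segmentation

The generator draws bundle orientations i.i.d. from a two-component axial
von Mises mixture (locations μ₁, μ₂, shared concentration κ of the
doubled-angle distribution, weight w). Bundles are rendered as anti-aliased
capsules (segment plus half-width, intensity falling off linearly over one
pixel) because only the orientation, not the true bundle morphology, is the
quantity under study, and elongated primitives have unambiguous principal
axes. Placement is rejection-sampled so capsule center-lines keep at least
the sum of half-widths plus a 2 px margin (segment–segment distances via
shapely), giving non-overlapping objects; the dermis is the band below a
gently curved near-horizontal epidermis polyline (sinusoid, default 3 px
amplitude). Default geometry: 200 bundles of length 30–60 px and width
4–8 px on a 600×800 canvas, background level 0.05 with Gaussian noise
SD 0.02.

Defaults for the two cohorts mirror the study conditions: greater mixture
weight 0.62 (healthy basket-weave) and 0.79 (fibrotic), peaks 90° apart at
45°/135°, κ = 8.

Segmentation thresholds with Otsu (fixed thresholds available), applies a
disk-radius-1 morphological opening, labels 8-connected components and
keeps regions above `min_area` (default 20 px²). Orientation is the
principal axis of the region's second-order central moments — closed-form,
and exact for symmetric elongated shapes. On default slides this recovers
100% of bundles with a maximum axial error well under 1°; the tested
contract is ≥95% recovery within 5°. What this does **not** emulate:
polarized-light birefringence, stain color variation, bundle branching and
merging, and overlapping bundles — real sections will segment worse, and
recovery there depends on the opaque identification step of the original
instrument software this pipeline replaces with an explicit, parameterized
one.

## Epidermis tracing and scalar metrics

The epidermal edge is traced column-by-column on the declared side of the
dermis mask (error on disconnected masks, with an explicit
largest-component fallback). Contour length is computed from chords taken
every 4th column plus a one-pixel end-cap. Single-pixel chords on a pixel
staircase overestimate sloped curves (≈8% at slope ½); subsampling averages
the ±0.5 px rounding out, and the end-cap makes a straight W-column edge
measure exactly W px. Validated against analytic oracles: a semicircular
boundary of radius 100 px measures πr within 0.3%, and the thickness
(area / epidermal contour length) of a 200×50 rectangle is exactly 50.
Contour length deliberately uses the epidermal boundary only, not the full
dermis perimeter, so thickness equals band height for a rectangular band.

Collagen fraction is |stain ∧ dermis| / |dermis| on binary masks — scale
invariant by construction.

## Two-peak decomposition

EM on doubled angles fits the 2-component von Mises mixture; log-densities
use exponentially scaled Bessel functions, concentrations are obtained from
the weighted resultant via the Best–Fisher approximation and capped at 10³
(beyond which the component is numerically a spike). Initialisation: first
restart at the two largest well-separated bins of a 5° histogram, remaining
restarts (5 total) at seeded uniform random locations; best log-likelihood
wins; tolerance 1e-6 on the log-likelihood, at most 500 iterations;
non-convergence is reported on the result, never silently dropped.
Components are sorted by weight, and weights on exact two-spike data reduce
to exact counted proportions (responsibilities saturate), which the tests
assert against brute-force counting.

If the fitted peak axes are closer than 20° the decomposition is flagged
degenerate and the score is 1.0 — a unimodal distribution is maximally
aligned by convention. The 20° threshold is a design choice (histogram
bins are 5°, κ = 8 peaks have ~13° half-width at half-maximum); it is
config-exposed. Mixture weights are soft (responsibility) fractions; a
nonparametric fallback (hard assignment to the two circular-KDE modes)
ships behind a config flag for sensitivity analysis, and agrees with EM to
a few percent on well-separated mixtures.

## Count model and signature workflow

Counts are negative-binomial: gene-and-sample mean μ with variance
μ + αμ² (default dispersion α = 0.05, baseline mean 100, per-gene log2
spread 1.0, per-sample size factors log-normal with SD 0.2). A planted gene
adds slope·z(metric) plus N(0, noise_sd²) to its log2 mean, where z is the
z-scored target metric; `slope_for_target_r2` inverts
r² = slope²/(slope² + σ²_total), with σ²_total the planted noise plus the
delta-method log2 variance of NB sampling, to plant genes at a chosen
population r² (default 0.8, noise SD 0.3). Group effects are explicit log2
fold changes on non-control samples; in the default study the planted
genes acquire their group difference through the metric shift between
cohorts, as they would in a real treated-vs-control design.

Normalization is median-of-ratios over genes positive in every sample
(error advising a pseudo-reference otherwise). The differential test is a
desk-scale substitute for a negative-binomial GLM: Welch t on
log2(normalized+1), BH adjustment across all genes, with the joint filters
mean normalized count strictly > 3 (mouse; 4 human), |FC| > 1.5 computed
on normalized group means with pseudocount 1, adjusted p < 0.05. Pooled
DEGs pass in any treatment-vs-control contrast. The substitute is exposed
behind `call_degs` so a heavier model can replace it without touching
filtering or intersection. Correlation defaults to Pearson on
log2(normalized+1) (linear scale optional; which scale the original
workflow used is not documented, and log is the stabler choice for
counts); zero-variance genes get r² = 0, a constant metric is an error.
An "expressed" prefilter (mean normalized count above the count threshold)
is applied before correlation. Null calibration is tested: with nothing
planted, the DEG pass fraction stays below α.

## Migration model and statistics

The trajectory simulator is a persistent random walk: headings evolve by
von Mises steps whose concentration is the inverse-resultant of the
persistence parameter (default 0.6); step lengths are gamma (shape 4) with
mean `speed_mean` (default 3 px per 8-min frame); frames every 8 minutes
for 4.5 hours (270 min, floored to 33 whole frames; the study config uses
272 min so the frame count divides evenly).
On an **aligned** substrate, contact guidance is modelled two ways at once:
each heading relaxes toward the nearer direction of the fiber axis by
fraction `alignment_bias` (default 0.35), and effective persistence rises
to 1−(1−p)(1−bias) — without the latter, direction reversals along the
fibers mute the displacement gain to a few percent, whereas guided cells
show a robust increase in both displacement and directionality (~44% and
~0.44 vs 0.30 at defaults). The knockdown factor scales step lengths, so
expected net displacement scales multiplicatively and exactly — the
estimand the control-normalized displacement recovers (default 0.75 on
aligned fibers only, matching a ~25% reduction with no effect on random
substrates).

Per-cell metrics: net displacement, accumulated distance, directionality
(net/accumulated; 0 for a zero-length path). Tracks spanning less than
half the movie are excluded and counted in QC (the cutoff is
config-exposed; no track-length filter is documented for the original
assay). The default group test is Welch's t on per-cell net displacement
(the original report gives a p-value without naming a test);
Mann–Whitney is an option. No drift correction is applied by default.
Whether "mean cell displacement" means the endpoint displacement averaged
over cells (assumed here) or a time-averaged quantity is ambiguous in the
source description; the endpoint reading is implemented.

## Problem sizes and determinism

Default study sizes — 4 slides × 200 bundles, 24 samples × 1000 genes
(30/30/20 planted), 4 × 150 cells × 35 frames — keep a full run under half
a minute on one CPU while leaving Monte-Carlo recovery tolerances
comfortably tight (mixture weights ±0.03 at n = 2000 angles; knockdown
±0.05 at n = 500 cells; type-I calibration over 1000 null replicates).
Every generator and the EM restarts take explicit seeds; identical
(parameters, seed) pairs are bit-identical, which the manifest checksums
and tests assert.

## Known limitations

- Capsule bundles and a single global mixture ignore spatially structured
  orientation fields, bundle curvature and overlap.
- The axial von Mises form for angle spread is a modelling convention; no
  distributional form is documented for real bundle-angle spread.
- The Welch-on-log substitute is not a NB GLM; at very low counts its
  p-values are conservative relative to DESeq2-style inference.
- The trajectory model has no cell–cell interactions, no confinement and
  homogeneous parameters per condition; real wells mix phenotypes.
- Passing tests demonstrate correctness of the computations and recovery
  under the generators' assumptions, not performance on real sections,
  libraries or movies.
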