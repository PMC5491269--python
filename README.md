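# dermaquant

Quantitative analysis of dermal fibrosis from three angles: collagen bundle
architecture in stained skin sections, transcriptomic signatures correlated
with histology, and fibroblast migration on engineered substrates.

In fibrotic skin (as in diffuse cutaneous systemic sclerosis or
bleomycin-induced dermal fibrosis), the healthy basket-weave arrangement of
dermal collagen — two interleaved bundle populations at distinct axes —
collapses toward a single aligned population. `dermaquant` quantifies this
and the downstream biology for image analysts and computational biologists
working with histology, bulk RNA-seq and time-lapse tracking data. Every
stage ships with a synthetic generator producing data with machine-readable
ground truth, so the whole pipeline is testable end to end without any
external download.

## The measurements

**Alignment score.** Collagen bundles are segmented from a stained section
(Otsu threshold, morphological opening, connected components) and each
bundle's axial orientation θ ∈ [0°, 180°) is taken from the principal axis
of its second-order central moments, then re-expressed relative to the
epidermis tangent. The angle distribution is decomposed into a
two-component axial von Mises mixture by EM on doubled angles
(θ → 2θ mod 360°):

p(θ) = w·vM(2θ; 2μ₁, κ₁) + (1−w)·vM(2θ; 2μ₂, κ₂)

The **alignment score is max(w, 1−w)** — the fraction of fibers within the
greater of the two angular peaks. A perfect basket-weave scores 0.5; fully
aligned collagen scores 1.0 (peaks closer than 20° are treated as one,
degenerate, peak).

**Dermal thickness** is dermis area divided by epidermal contour length
(equal to band height for a rectangular band); **total collagen** is the
stain-positive fraction of the dermis mask.

**Gene signatures.** Counts are normalized by median-of-ratios size
factors; differentially expressed genes (DEGs) must jointly satisfy mean
normalized count > 3 (mouse preset; 4 for human), |fold change| > 1.5 and
Benjamini–Hochberg adjusted p < 0.05, pooled over every
treatment-vs-control contrast. Each expressed gene's squared Pearson
correlation r² with each histology metric is computed on
log2(normalized+1); the signature of a metric is
{r² > cutoff} ∩ {DEG}, with cutoffs 0.7 / 0.4 / 0.4 for thickness /
collagen / alignment, and "unique" genes belong to exactly one signature.

**Migration statistics.** From tracked positions (8-minute frames, 4.5 h):
per-cell net displacement, accumulated distance and directionality
(net/accumulated); group means, knockdown displacement normalized to the
control siRNA, and a Welch t-test (Mann–Whitney optional) between
conditions.

## Worked example

Run the numbered analysis scripts (or equivalently `dermaquant full`) to
reproduce the synthetic study:

```bash
python analysis/01_simulate_study.py
python analysis/02_histology_metrics.py
python analysis/03_alignment_scores.py
python analysis/04_gene_signatures.py
python analysis/05_migration_assay.py
```

`03_alignment_scores.py` prints, for two healthy and two fibrotic slides of
200 bundles each:

```
           slide   cohort  true_w    score       mu1        mu2  converged
 slide_healthy_0  healthy    0.62 0.630000 44.388281 135.078477       True
 slide_healthy_1  healthy    0.62 0.645004 45.765141 135.864124       True
slide_fibrotic_0 fibrotic    0.79 0.805203 45.701661 135.733156       True
slide_fibrotic_1 fibrotic    0.79 0.789996 44.318675 137.153134       True
```

The fitted score recovers each cohort's true mixture weight (0.62
basket-weave-like, 0.79 fibrotic) to within sampling error, and the peak
locations recover the planted 45°/135° axes. `05_migration_assay.py`
prints:

```
aligned: knockdown/control displacement ratio 0.758 (Welch p = 2.90e-05)
random: knockdown/control displacement ratio 0.976 (Welch p = 6.81e-01)
```

i.e. the simulated knockdown (factor 0.75) reduces mean displacement by
~24% on aligned fibers and does nothing on random fibers — exactly the
planted effect. `04_gene_signatures.py` reports 80 pooled DEGs among 1000
genes and signatures of 30/73/75 genes for thickness/collagen/alignment
(the collagen and alignment signatures overlap heavily because those
metrics co-vary across the simulated cohorts).

Each stage is also a library call (`dermaquant.pipeline.run_*`) and a CLI
subcommand (`dermaquant simulate|histology|align|signature|migrate|full`,
exit codes 0/2/3 for success/config error/stage failure), configured by a
YAML file mirroring `dermaquant.pipeline.PipelineConfig`.

## Output schemas

- slides: 8-bit TIFF + `*_truth.csv` (bundle_id, cx, cy, length_px,
  width_px, theta_deg) + `*_epidermis.csv` (x, y)
- bundle tables: CSV (bundle_id, cx, cy, area_px2, theta_deg,
  eccentricity, theta_rel_deg)
- counts: TSV genes × samples; `metrics.csv` (sample, thickness,
  alignment, collagen, group); `truth_genes.csv` planted-gene membership
- alignment: CSV/JSON per slide (mu1, mu2, w1, w2, kappa1, kappa2, score,
  converged) and an angle-histogram PNG
- trajectories: long CSV (cell_id, t_min, x_px, y_px, well, condition);
  per-cell and per-group stats CSVs and a comparison JSON
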