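"""Build histology-correlated gene signatures from the simulated counts.

Normalizes the count matrix (median-of-ratios), calls pooled DEGs
(mouse criteria: mean normalized count > 3, |FC| > 1.5, BH-adjusted
p < 0.05), correlates every expressed gene to each histology metric, and
intersects genes above the r² cutoffs (thickness 0.7, collagen 0.4,
alignment 0.4) with the DEG set.
"""

import argparse

from dermaquant.pipeline import PipelineConfig, run_signature


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/study")
    args = parser.parse_args()

    cfg = PipelineConfig(outdir=args.outdir)
    result = run_signature(cfg)
    summary = result["summary"]
    print(f"pooled DEGs: {summary['n_degs']} of {summary['n_expressed']} expressed genes")
    for metric in ("thickness", "collagen", "alignment"):
        s = summary[metric]
        print(f"{metric:>10} signature: {s['n_genes']:3d} genes ({s['n_unique']} unique)")


if __name__ == "__main__":
    main()
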