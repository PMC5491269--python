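"""Score collagen bundle alignment per slide via the two-peak decomposition.

Fits the two-component axial von Mises mixture to each slide's
epidermis-relative bundle angles and reports the alignment score (fraction
of fibers in the greater peak) against the generator's true mixture weight.
Healthy basket-weave slides should score near 0.62, fibrotic slides near
0.79.
"""

import argparse

from dermaquant.pipeline import PipelineConfig, run_align


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/study")
    args = parser.parse_args()

    cfg = PipelineConfig(outdir=args.outdir)
    table = run_align(cfg)
    cols = ["slide", "cohort", "true_w", "score", "mu1", "mu2", "converged"]
    print(table[[c for c in cols if c in table.columns]].to_string(index=False))
    by_cohort = table.groupby("cohort")["score"].mean()
    print("\nmean score by cohort:")
    print(by_cohort.to_string())


if __name__ == "__main__":
    main()
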