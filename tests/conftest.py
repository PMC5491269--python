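import numpy as np
import pandas as pd
import pytest

from dermaquant import signature, synthetic


@pytest.fixture(scope="session")
def basket_weave_slide():
    """One 200-bundle basket-weave slide with ground truth (shared, read-only)."""
    spec = synthetic.OrientationMixtureSpec(mu1=45.0, mu2=135.0, kappa=8.0, w=0.62)
    return synthetic.generate_slide(spec, n_bundles=200, canvas=(600, 800), seed=42)


@pytest.fixture()
def toy_deg_matrix():
    """Hand-built 6-gene x 6-sample matrix with known DEG outcome.

    Size factors are exactly 1 by construction (flat genes pin the
    median-of-ratios), the two planted 4-fold genes pass the mouse criteria
    and the boundary gene sits at mean normalized count exactly 3.0.
    """
    counts = pd.DataFrame(
        {
            "s1": [100, 400, 1, 50, 20, 10],
            "s2": [110, 440, 1, 50, 20, 10],
            "s3": [90, 360, 1, 50, 20, 10],
            "s4": [400, 100, 4, 50, 20, 10],
            "s5": [440, 110, 5, 50, 20, 10],
            "s6": [360, 90, 6, 50, 20, 10],
        },
        index=["g_up", "g_down", "g_boundary", "g_flat1", "g_flat2", "g_flat3"],
    )
    groups = pd.Series(["ctrl"] * 3 + ["treat"] * 3, index=counts.columns)
    return signature.CountMatrix(counts=counts, groups=groups)


@pytest.fixture(scope="session")
def cohort_count_matrix():
    """24-sample matrix with 30 planted alignment genes among 1000 (shared)."""
    rng = np.random.default_rng(7)
    samples = [f"s{i:02d}" for i in range(24)]
    metrics = pd.DataFrame(
        {
            "alignment": np.clip(
                np.r_[rng.normal(0.62, 0.04, 12), rng.normal(0.82, 0.04, 12)],
                0.5,
                0.98,
            ),
            "thickness": np.r_[rng.normal(40, 4, 12), rng.normal(60, 6, 12)],
        },
        index=samples,
    )
    groups = pd.Series(["saline"] * 12 + ["bleomycin"] * 12, index=samples)
    slope = synthetic.slope_for_target_r2(0.8)
    planted = {f"align{i:03d}": ("alignment", slope, 0.3) for i in range(30)}
    spec = synthetic.SignatureSpec(n_genes=1000, planted_genes=planted)
    matrix, truth, _ = synthetic.generate_counts(spec, metrics, groups, seed=11)
    return matrix, metrics, truth
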