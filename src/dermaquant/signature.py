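"""Histology-correlated gene signatures from count matrices.

The workflow: normalize counts (median-of-ratios size factors), call
differentially expressed genes (DEGs) for every treatment-vs-control
contrast under joint count / fold-change / adjusted-p criteria, correlate
every expressed gene to each per-sample histology metric (dermis thickness,
collagen bundle alignment, total collagen fraction), and intersect the
highly-correlated genes with the pooled DEG set to obtain one gene signature
per metric. "Unique" genes belong to exactly one metric's signature.

The differential test is a desk-scale Welch t-test on log2(normalized + 1)
with Benjamini-Hochberg adjustment; it is exposed behind ``call_degs`` so a
heavier negative-binomial GLM could be swapped in without touching the
filtering or intersection logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DEGCriteria",
    "MOUSE_CRITERIA",
    "HUMAN_CRITERIA",
    "MetricSignature",
    "normalize_counts",
    "bh_adjust",
    "call_degs",
    "call_degs_pooled",
    "correlate_to_metric",
    "build_signatures",
]


@dataclass
class CountMatrix:
    """Gene-by-sample raw counts with a treatment label per sample.

    ``counts``: DataFrame, rows = gene ids, columns = sample ids,
    nonnegative integers. ``groups``: Series indexed by sample id.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("counts must be finite and nonnegative")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def genes(self):
        return self.counts.index

    @property
    def samples(self):
        return self.counts.columns


@dataclass(frozen=True)
class DEGCriteria:
    """Joint filters a gene must pass to count as differentially expressed."""

    min_norm_count: float = 3.0  # mouse preset; human data uses 4
    min_abs_fc: float = 1.5
    alpha: float = 0.05
    adjust: str = "bh"

    def __post_init__(self):
        if self.min_abs_fc <= 1:
            raise ValueError("min_abs_fc must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


MOUSE_CRITERIA = DEGCriteria(min_norm_count=3.0)
HUMAN_CRITERIA = DEGCriteria(min_norm_count=4.0)


@dataclass
class MetricSignature:
    """Genes both differentially expressed and correlated with one metric."""

    metric: str
    genes: set = field(default_factory=set)
    unique_genes: set = field(default_factory=set)


def normalize_counts(counts: pd.DataFrame | CountMatrix):
    """Median-of-ratios normalization.

    Size factor of a sample = median over all-positive genes of the ratio of
    that sample's count to the gene's geometric mean across samples.
    Normalized count = raw count / size factor.

    Returns (normalized DataFrame, size factors Series).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    vals = counts.to_numpy(dtype=float)
    positive = np.all(vals > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply a "
            "pseudo-reference (e.g. add a constant housekeeping row) first"
        )
    ref = np.exp(np.mean(np.log(vals[positive]), axis=1))  # geometric means
    sf = np.median(vals[positive] / ref[:, None], axis=0)
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    return counts / size_factors, size_factors


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    Adjusted p of the i-th smallest p (rank i of m) is
    min over j >= i of (m / j) * p_(j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def _welch_log2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values on log2(x+1).

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means agree and p = 0 when they differ, instead of noise-driven values.
    """
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    degenerate = (var_a + var_b) < 1e-20
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)
    same_mean = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    return np.where(degenerate, np.where(same_mean, 1.0, 0.0), p)


def call_degs(
    m: CountMatrix,
    contrast: tuple[str, str],
    crit: DEGCriteria = MOUSE_CRITERIA,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression table for one group contrast.

    ``contrast`` = (reference group, treatment group). Fold change is
    computed on normalized group means with pseudocount 1 (treatment over
    reference); the test is Welch t on log2(normalized + 1), adjusted by BH
    across all genes in the matrix. A gene passes iff its mean normalized
    count (over the contrast samples) strictly exceeds ``min_norm_count``,
    |FC| > ``min_abs_fc`` and adjusted p < ``alpha``.
    """
    ref_label, trt_label = contrast
    for label in contrast:
        if (m.groups == label).sum() < 2:
            raise ValueError(f"group {label!r} needs at least 2 samples")
    norm = normalize_counts(m)[0] if normalized is None else normalized
    ref = norm.loc[:, m.groups[m.groups == ref_label].index].to_numpy(dtype=float)
    trt = norm.loc[:, m.groups[m.groups == trt_label].index].to_numpy(dtype=float)

    mean_ref, mean_trt = ref.mean(axis=1), trt.mean(axis=1)
    mean_norm = np.concatenate([ref, trt], axis=1).mean(axis=1)
    log2fc = np.log2((mean_trt + 1.0) / (mean_ref + 1.0))
    p = _welch_log2(ref, trt)
    p_adj = bh_adjust(p)
    passed = (
        (mean_norm > crit.min_norm_count)
        & (np.abs(log2fc) > np.log2(crit.min_abs_fc))
        & (p_adj < crit.alpha)
    )
    return pd.DataFrame(
        {
            "mean_norm_count": mean_norm,
            "mean_ref": mean_ref,
            "mean_trt": mean_trt,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "passed": passed,
        },
        index=m.genes,
    )


def call_degs_pooled(
    m: CountMatrix,
    control_group: str,
    crit: DEGCriteria = MOUSE_CRITERIA,
) -> pd.DataFrame:
    """Pool DEG calls over every treatment-vs-control contrast.

    A gene is a pooled DEG if it passes the criteria in ANY of the
    comparisons against the control group. Returns a table with one
    ``passed_<group>`` column per contrast plus ``passed`` (the union).
    """
    labels = [g for g in pd.unique(m.groups) if g != control_group]
    if control_group not in set(m.groups):
        raise ValueError(f"control group {control_group!r} absent from matrix")
    if not labels:
        raise ValueError("need at least one non-control group")
    norm, _ = normalize_counts(m)
    out = pd.DataFrame(index=m.genes)
    passed_any = np.zeros(len(m.genes), dtype=bool)
    for g in labels:
        table = call_degs(m, (control_group, g), crit, normalized=norm)
        out[f"passed_{g}"] = table["passed"]
        out[f"log2fc_{g}"] = table["log2fc"]
        passed_any |= table["passed"].to_numpy()
    out["passed"] = passed_any
    return out


def correlate_to_metric(
    normalized: pd.DataFrame,
    metric: pd.Series,
    scale: str = "log",
) -> pd.DataFrame:
    """Squared Pearson correlation of every gene with one histology metric.

    ``scale`` chooses the expression scale: "log" = log2(normalized + 1)
    (default), "linear" = normalized counts. Genes with zero variance get
    r² = 0 by convention. Returns a DataFrame (r2, sign) indexed by gene.
    """
    metric = metric.reindex(normalized.columns)
    if metric.isna().any():
        raise ValueError("metric missing for some samples")
    if len(metric) < 4:
        raise ValueError("need at least 4 samples for per-gene correlation")
    y = metric.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("metric is constant across samples; correlation undefined")
    if scale == "log":
        x = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    elif scale == "linear":
        x = normalized.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)
    return pd.DataFrame(
        {"r2": r**2, "sign": np.sign(r)}, index=normalized.index
    )


def build_signatures(
    correlations: dict[str, pd.DataFrame],
    deg_pass: pd.Series,
    thresholds: dict[str, float] | None = None,
) -> dict[str, MetricSignature]:
    """Intersect metric-correlated genes with DEGs into per-metric signatures.

    ``correlations`` maps metric name → correlate_to_metric output;
    ``deg_pass`` is a boolean Series over the same gene universe;
    ``thresholds`` maps metric name → r² cutoff (defaults: thickness 0.7,
    collagen 0.4, alignment 0.4). A metric's signature is
    {g : r²(g) > cutoff} ∩ {g : DEG}; its unique set removes genes present
    in any other metric's signature.
    """
    if thresholds is None:
        thresholds = {"thickness": 0.7, "collagen": 0.4, "alignment": 0.4}
    unknown = set(thresholds) - set(correlations)
    if unknown:
        raise ValueError(f"thresholds given for unknown metrics: {sorted(unknown)}")
    deg_genes = set(deg_pass.index[deg_pass.astype(bool)])
    signatures: dict[str, MetricSignature] = {}
    for metric, cutoff in thresholds.items():
        corr = correlations[metric]
        hits = set(corr.index[corr["r2"] > cutoff]) & deg_genes
        signatures[metric] = MetricSignature(metric=metric, genes=hits)
    for metric, sig in signatures.items():
        others = set().union(
            *(s.genes for name, s in signatures.items() if name != metric)
        )
        sig.unique_genes = sig.genes - others
    return signatures
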