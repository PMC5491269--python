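"""Synthetic study data with machine-readable ground truth.

Three generators emulate the data types of the analysis:

* **Slides** — picrosirius-red-like stain images: elongated collagen-bundle
  capsules drawn below a gently curved epidermis, bundle orientations drawn
  i.i.d. from a two-component axial von Mises mixture (balanced bimodal =
  basket-weave; skewed/unimodal = fibrotic).
* **Count matrices** — negative-binomial gene counts with per-sample size
  factors and a set of planted genes whose log2 expression is linear in one
  histology metric, so correlation-signature recovery can be scored exactly.
* **Trajectories** — a persistent random walk with von Mises heading noise,
  axial attraction toward the fiber axis on aligned substrates, and a
  multiplicative knockdown factor on step size, imaged at fixed intervals.

Every generator takes an explicit seed and is deterministic given
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .axial import kappa_from_resultant, wrap_axial
from .signature import CountMatrix

__all__ = [
    "OrientationMixtureSpec",
    "BundleGeometry",
    "SyntheticSlide",
    "SignatureSpec",
    "TrajectoryParams",
    "sample_orientations",
    "generate_slide",
    "generate_counts",
    "slope_for_target_r2",
    "generate_trajectories",
    "write_slide",
    "write_counts",
    "write_trajectories",
]


# --------------------------------------------------------------------------
# slides
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationMixtureSpec:
    """Two-component axial von Mises mixture of bundle orientations.

    ``w`` is the weight of component 1 — the ground-truth counterpart of the
    alignment score when it is the greater weight. Angles are axial
    (θ ≡ θ + 180°); ``kappa`` is the concentration of the doubled-angle
    von Mises.
    """

    mu1: float
    mu2: float
    kappa: float
    w: float = 0.5
    unimodal: bool = False

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if (
            not self.unimodal
            and self.w not in (0.0, 1.0)
            and wrap_axial(self.mu1) == wrap_axial(self.mu2)
        ):
            raise ValueError("mu1 == mu2 requires unimodal=True")


@dataclass(frozen=True)
class BundleGeometry:
    """Size ranges (pixels) for the capsule primitives standing in for bundles."""

    length_range: tuple[float, float] = (30.0, 60.0)
    width_range: tuple[float, float] = (4.0, 8.0)


@dataclass
class SyntheticSlide:
    """A histology-like image plus its full ground truth.

    ``truth_bundles`` columns: bundle_id, cx, cy, length_px, width_px,
    theta_deg (axial, [0, 180), measured from +x with y pointing down).
    ``epidermis_polyline`` is an ordered (x, y) array tracing the upper
    dermis boundary left to right; ``band_height`` is the dermis band
    thickness used by the generator.
    """

    image: np.ndarray
    dermis_mask: np.ndarray
    epidermis_polyline: np.ndarray
    truth_bundles: pd.DataFrame
    seed: int
    band_height: float


def sample_orientations(spec: OrientationMixtureSpec, n: int, rng) -> np.ndarray:
    """Draw n axial angles (degrees in [0, 180)) from the mixture."""
    comp1 = rng.random(n) < spec.w
    mu = np.where(comp1, spec.mu1, spec.mu2)
    phi = rng.vonmises(np.deg2rad(2.0 * mu), spec.kappa)
    return wrap_axial(np.rad2deg(phi) / 2.0)


def _capsule_clear(p0, p1, halfwidth, placed_lines, placed_halfwidths, margin):
    """True when a candidate capsule overlaps none of the placed ones."""
    if not placed_lines:
        return True
    cand = shapely.LineString([p0, p1])
    dists = shapely.distance(cand, np.array(placed_lines, dtype=object))
    return bool(np.all(dists > halfwidth + np.asarray(placed_halfwidths) + margin))


def _render_capsule(image, p0, p1, halfwidth):
    """Max-composite an anti-aliased capsule (segment + half-width) in place."""
    h, w = image.shape
    x0 = max(int(np.floor(min(p0[0], p1[0]) - halfwidth - 1)), 0)
    x1 = min(int(np.ceil(max(p0[0], p1[0]) + halfwidth + 1)) + 1, w)
    y0 = max(int(np.floor(min(p0[1], p1[1]) - halfwidth - 1)), 0)
    y1 = min(int(np.ceil(max(p0[1], p1[1]) + halfwidth + 1)) + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.stack([xs - p0[0], ys - p0[1]], axis=-1)
    seg = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    seg_len2 = seg @ seg
    t = np.clip((d @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = np.stack([p0[0] + t * seg[0], p0[1] + t * seg[1]], axis=-1)
    dist = np.hypot(xs - closest[..., 0], ys - closest[..., 1])
    intensity = np.clip(halfwidth + 0.5 - dist, 0.0, 1.0)
    np.maximum(image[y0:y1, x0:x1], intensity, out=image[y0:y1, x0:x1])


def generate_slide(
    spec: OrientationMixtureSpec,
    n_bundles: int,
    geometry: BundleGeometry = BundleGeometry(),
    canvas: tuple[int, int] = (600, 800),
    seed: int = 0,
    epidermis_depth: float = 30.0,
    epidermis_amplitude: float = 3.0,
    band_height: float | None = None,
    background_level: float = 0.05,
    noise_sd: float = 0.02,
    overlap_margin: float = 2.0,
    max_tries: int = 500,
) -> SyntheticSlide:
    """Generate a stained-slide image with non-overlapping bundle capsules.

    The epidermis is a gently curved near-horizontal polyline at the top of
    the canvas; the dermis is the band of ``band_height`` pixels below it
    (default: down to the bottom edge). Bundle orientations are i.i.d. draws
    from ``spec``; placement is rejection-sampled so capsules never overlap.

    Coordinates: pixel centers, origin top-left, x rightward, y downward;
    orientation θ means the capsule axis points along (cos θ, sin θ).
    """
    h, w = canvas
    if n_bundles < 1:
        raise ValueError("n_bundles must be >= 1")
    lmin, lmax = geometry.length_range
    wmin, wmax = geometry.width_range
    rng = np.random.default_rng(seed)

    y_top = epidermis_depth + epidermis_amplitude
    depth = h - 1 if band_height is None else y_top + band_height
    if depth > h - 1:
        raise ValueError("band_height exceeds the canvas")
    if lmax + 2 * wmax >= min(w, depth - y_top):
        raise ValueError("canvas too small for the requested bundle length")

    xs_all = np.arange(w, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    y_epi = epidermis_depth + epidermis_amplitude * np.sin(
        2.0 * np.pi * xs_all / w + phase
    )
    epidermis_polyline = np.column_stack([xs_all, y_epi])

    ys_grid = np.arange(h, dtype=float)[:, None]
    dermis_mask = (ys_grid > y_epi[None, :]) & (ys_grid <= depth)

    theta = sample_orientations(spec, n_bundles, rng)
    lengths = rng.uniform(lmin, lmax, n_bundles)
    widths = rng.uniform(wmin, wmax, n_bundles)

    image = np.clip(
        background_level + noise_sd * rng.standard_normal((h, w)), 0.0, 1.0
    )
    placed_lines: list[shapely.LineString] = []
    placed_hw: list[float] = []
    rows = []
    for i in range(n_bundles):
        half_len = lengths[i] / 2.0
        hw = widths[i] / 2.0
        u = np.array([np.cos(np.deg2rad(theta[i])), np.sin(np.deg2rad(theta[i]))])
        placed = False
        for _ in range(max_tries):
            cx = rng.uniform(hw + 1, w - hw - 2)
            cy = rng.uniform(y_top + hw + 1, depth - hw - 1)
            p0 = np.array([cx, cy]) - half_len * u
            p1 = np.array([cx, cy]) + half_len * u
            inside = all(
                hw + 1 <= p[0] <= w - hw - 2
                and y_epi[int(round(np.clip(p[0], 0, w - 1)))] + hw + 1 <= p[1] <= depth - hw - 1
                for p in (p0, p1)
            )
            if inside and _capsule_clear(
                p0, p1, hw, placed_lines, placed_hw, overlap_margin
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place bundle {i} without overlap; "
                "reduce n_bundles or enlarge the canvas"
            )
        placed_lines.append(shapely.LineString([p0, p1]))
        placed_hw.append(hw)
        _render_capsule(image, p0, p1, hw)
        rows.append((i, cx, cy, lengths[i], widths[i], theta[i]))

    truth = pd.DataFrame(
        rows, columns=["bundle_id", "cx", "cy", "length_px", "width_px", "theta_deg"]
    )
    return SyntheticSlide(
        image=image,
        dermis_mask=dermis_mask,
        epidermis_polyline=epidermis_polyline,
        truth_bundles=truth,
        seed=seed,
        band_height=float(depth - epidermis_depth),
    )


# --------------------------------------------------------------------------
# count matrices
# --------------------------------------------------------------------------

@dataclass
class SignatureSpec:
    """Design of a synthetic count matrix with planted metric-correlated genes.

    ``planted_genes`` maps gene id → (metric name, log2 slope per metric SD,
    extra log2 noise SD). ``group_effects`` maps gene id → log2 fold change
    applied to non-control samples. Background genes are independent of the
    metrics.
    """

    n_genes: int
    planted_genes: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    group_effects: dict[str, float] = field(default_factory=dict)
    gene_spread_log2: float = 1.0
    size_factor_spread: float = 0.2

    def __post_init__(self):
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(self.planted_genes) > self.n_genes:
            raise ValueError("more planted genes than the gene universe")


def slope_for_target_r2(
    target_r2: float,
    noise_sd: float = 0.3,
    baseline_mean: float = 100.0,
    dispersion: float = 0.05,
) -> float:
    """Log2 slope per metric SD giving an expected squared correlation.

    The population r² between a planted gene's log expression and its metric
    is slope² / (slope² + σ²_total), where σ²_total combines the planted
    log2 noise and the delta-method log2 variance of negative-binomial
    sampling, (log2 e)² (1/μ + α).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    nb_var = (np.log2(np.e)) ** 2 * (1.0 / baseline_mean + dispersion)
    total = noise_sd**2 + nb_var
    return float(np.sqrt(target_r2 / (1.0 - target_r2) * total))


def generate_counts(
    sig: SignatureSpec,
    metrics: pd.DataFrame,
    groups: pd.Series,
    seed: int = 0,
    control_group: str | None = None,
):
    """Draw a negative-binomial count matrix with planted structure.

    ``metrics`` is a per-sample table (rows = samples) of histology metric
    values; planted genes get log2 mean expression linear in the z-scored
    target metric. Returns (CountMatrix, truth DataFrame, size_factors).
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    groups = groups.reindex(metrics.index)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} needs at least 3 samples")
    for gene, (metric, _, _) in sig.planted_genes.items():
        if metric not in metrics.columns:
            raise ValueError(f"planted gene {gene!r} targets unknown metric {metric!r}")
    control = labels[0] if control_group is None else control_group

    rng = np.random.default_rng(seed)
    planted_ids = list(sig.planted_genes)
    n_bg = sig.n_genes - len(planted_ids)
    genes = planted_ids + [f"bg{i:04d}" for i in range(n_bg)]
    samples = list(metrics.index)
    n_s = len(samples)

    z = (metrics - metrics.mean()) / metrics.std(ddof=0)
    size_factors = np.exp(rng.normal(0.0, sig.size_factor_spread, n_s))
    treated = (groups != control).to_numpy()

    base = np.log2(sig.baseline_mean) + rng.normal(
        0.0, sig.gene_spread_log2, len(genes)
    )
    log2mu = np.tile(base[:, None], (1, n_s))
    for gi, gene in enumerate(genes):
        if gene in sig.planted_genes:
            metric, slope, noise_sd = sig.planted_genes[gene]
            log2mu[gi] += slope * z[metric].to_numpy()
            if noise_sd > 0:
                log2mu[gi] += rng.normal(0.0, noise_sd, n_s)
        if gene in sig.group_effects:
            log2mu[gi] += sig.group_effects[gene] * treated
    mu = 2.0**log2mu * size_factors[None, :]

    n_param = 1.0 / sig.dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=pd.Series(groups.to_numpy(), index=samples, name="group"),
    )
    truth = pd.DataFrame(
        [
            (g, m, s, nsd)
            for g, (m, s, nsd) in sig.planted_genes.items()
        ],
        columns=["gene", "metric", "slope", "noise_sd"],
    )
    sf = pd.Series(size_factors, index=samples, name="size_factor")
    return matrix, truth, sf


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryParams:
    """Persistent-random-walk parameters for one imaging condition.

    ``persistence`` is the mean resultant length of the per-step turning
    distribution (0 = uncorrelated, → 1 = ballistic). On an "aligned"
    substrate contact guidance both relaxes each heading toward the nearer
    direction of the fiber ``axis`` by fraction ``alignment_bias`` and
    raises the effective persistence to 1 − (1 − p)(1 − bias), suppressing
    direction reversals along the fibers. ``knockdown_factor`` scales
    step lengths multiplicatively (1 = control), modelling an siRNA effect
    on motility. dt and duration default to 8-minute frames for 4.5 hours.
    """

    n_cells: int
    dt: float = 8.0
    duration: float = 270.0
    speed_mean: float = 3.0
    persistence: float = 0.6
    substrate: str = "random"
    axis: float = 0.0
    knockdown_factor: float = 1.0
    alignment_bias: float = 0.35
    well: str = "w00"
    condition: str | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if not 0.0 < self.knockdown_factor <= 1.0:
            raise ValueError("knockdown_factor must lie in (0, 1]")
        if self.substrate not in ("aligned", "random"):
            raise ValueError("substrate must be 'aligned' or 'random'")


def generate_trajectories(params: TrajectoryParams, seed: int = 0) -> pd.DataFrame:
    """Simulate tracked cell positions; long format, one row per (cell, frame).

    Columns: cell_id, t_min, x_px, y_px, well, condition. Each cell has
    floor(duration / dt) + 1 positions starting at the origin-centered
    random spawn points.
    """
    n_steps = int(params.duration // params.dt)
    rng = np.random.default_rng(seed)
    n = params.n_cells
    p_eff = params.persistence
    if params.substrate == "aligned":  # contact guidance raises persistence
        p_eff = 1.0 - (1.0 - p_eff) * (1.0 - params.alignment_bias)
    kappa_p = kappa_from_resultant(p_eff)
    axis_rad = np.deg2rad(params.axis)

    pos = rng.uniform(0.0, 500.0, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, n)
    scale = params.speed_mean * params.knockdown_factor

    xs = np.empty((n_steps + 1, n))
    ys = np.empty((n_steps + 1, n))
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for step in range(1, n_steps + 1):
        if kappa_p > 0:
            heading = rng.vonmises(heading, kappa_p)
        else:
            heading = rng.uniform(-np.pi, np.pi, n)
        if params.substrate == "aligned":
            # axial relaxation toward the nearer of axis / axis + 180°
            delta = ((heading - axis_rad + np.pi / 2) % np.pi) - np.pi / 2
            heading = heading - params.alignment_bias * delta
        step_len = rng.gamma(4.0, scale / 4.0, n) if scale > 0 else np.zeros(n)
        pos = pos + step_len[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        xs[step], ys[step] = pos[:, 0], pos[:, 1]

    condition = (
        params.condition if params.condition is not None else params.substrate
    )
    t = np.arange(n_steps + 1) * params.dt
    frames = pd.DataFrame(
        {
            "cell_id": np.repeat([f"c{i:04d}" for i in range(n)], n_steps + 1),
            "t_min": np.tile(t, n),
            "x_px": xs.T.ravel(),
            "y_px": ys.T.ravel(),
            "well": params.well,
            "condition": condition,
        }
    )
    return frames


# --------------------------------------------------------------------------
# writers (all plain-text except the TIFF image)
# --------------------------------------------------------------------------

def write_slide(slide: SyntheticSlide, prefix):
    """Write image (8-bit TIFF), truth CSV and epidermis CSV; returns paths."""
    import tifffile

    prefix = str(prefix)
    img_path = prefix + ".tif"
    tifffile.imwrite(img_path, (slide.image * 255).astype(np.uint8))
    truth_path = prefix + "_truth.csv"
    slide.truth_bundles.to_csv(truth_path, index=False)
    epi_path = prefix + "_epidermis.csv"
    pd.DataFrame(slide.epidermis_polyline, columns=["x", "y"]).to_csv(
        epi_path, index=False
    )
    return img_path, truth_path, epi_path


def write_counts(matrix: CountMatrix, metrics: pd.DataFrame, truth: pd.DataFrame, outdir):
    """Write counts TSV, metrics+group CSV and planted-gene truth CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / "counts.tsv"
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    meta = metrics.copy()
    meta["group"] = matrix.groups
    metrics_path = outdir / "metrics.csv"
    meta.to_csv(metrics_path, index_label="sample")
    truth_path = outdir / "truth_genes.csv"
    truth.to_csv(truth_path, index=False)
    return counts_path, metrics_path, truth_path


def write_trajectories(frames: pd.DataFrame, path):
    frames.to_csv(path, index=False)
    return path
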