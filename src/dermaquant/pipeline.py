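"""End-to-end synthetic study: simulate → histology → alignment → signature → migration.

Stage functions share a :class:`PipelineConfig` (YAML round-trippable) and
write plain-text tables plus a JSON report under the configured output
directory, so the whole analysis is reproducible from one config and its
per-stage seeds. The defaults encode the study conditions: a healthy cohort
with balanced basket-weave mixtures (greater weight 0.62) versus a fibrotic
cohort skewed to one peak (0.79); treated-vs-control count matrices with
planted metric-correlated genes; and migration assays on aligned versus
random substrates where the knockdown reduces displacement on aligned
fibers only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as alignment_mod
from . import histology as histology_mod
from . import migration as migration_mod
from . import signature as signature_mod
from . import synthetic

logger = logging.getLogger("dermaquant")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_histology",
    "run_align",
    "run_signature",
    "run_migrate",
    "run_full",
]


@dataclass
class SlideSimOptions:
    n_slides_per_cohort: int = 2
    n_bundles: int = 200
    canvas: tuple[int, int] = (600, 800)
    kappa: float = 8.0
    mu1: float = 45.0
    mu2: float = 135.0
    cohort_weights: dict = field(
        default_factory=lambda: {"healthy": 0.62, "fibrotic": 0.79}
    )


@dataclass
class CountSimOptions:
    n_samples_per_group: int = 12
    n_genes: int = 1000
    planted_per_metric: dict = field(
        default_factory=lambda: {"alignment": 30, "thickness": 30, "collagen": 20}
    )
    target_r2: float = 0.8
    noise_sd: float = 0.3
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    control_group: str = "saline"
    treated_group: str = "bleomycin"


@dataclass
class TrajectorySimOptions:
    n_cells: int = 150
    dt: float = 8.0
    duration: float = 272.0
    speed_mean: float = 3.0
    persistence: float = 0.6
    knockdown_factor: float = 0.75
    control_sirna: str = "siControl"
    knockdown_sirna: str = "siArhgdib"


@dataclass
class HistologyOptions:
    threshold: str = "otsu"
    min_area: float = 20.0
    opening_radius: int = 1
    angle_reference: str = "global"


@dataclass
class AlignmentOptions:
    n_starts: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    min_separation: float = 20.0
    method: str = "em"  # or "nearest_mode" (nonparametric fallback)


@dataclass
class SignatureOptions:
    species: str = "mouse"  # mouse: normalized counts > 3; human: > 4
    r2_thresholds: dict = field(
        default_factory=lambda: {"thickness": 0.7, "collagen": 0.4, "alignment": 0.4}
    )
    correlation_scale: str = "log"


@dataclass
class MigrationOptions:
    test: str = "welch"
    min_span_fraction: float = 0.5


@dataclass
class PipelineConfig:
    outdir: str = "results/study"
    seeds: dict = field(
        default_factory=lambda: {
            "slides": 101,
            "counts": 202,
            "trajectories": 303,
            "alignment": 404,
        }
    )
    slides: SlideSimOptions = field(default_factory=SlideSimOptions)
    counts: CountSimOptions = field(default_factory=CountSimOptions)
    trajectories: TrajectorySimOptions = field(default_factory=TrajectorySimOptions)
    histology: HistologyOptions = field(default_factory=HistologyOptions)
    alignment: AlignmentOptions = field(default_factory=AlignmentOptions)
    signature: SignatureOptions = field(default_factory=SignatureOptions)
    migration: MigrationOptions = field(default_factory=MigrationOptions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data.pop(f.name)
            if dataclasses.is_dataclass(f.type) or f.name in (
                "slides",
                "counts",
                "trajectories",
                "histology",
                "alignment",
                "signature",
                "migration",
            ):
                sub_cls = {
                    "slides": SlideSimOptions,
                    "counts": CountSimOptions,
                    "trajectories": TrajectorySimOptions,
                    "histology": HistologyOptions,
                    "alignment": AlignmentOptions,
                    "signature": SignatureOptions,
                    "migration": MigrationOptions,
                }.get(f.name)
                if sub_cls is not None and isinstance(value, dict):
                    known = {x.name for x in dataclasses.fields(sub_cls)}
                    unknown = set(value) - known
                    if unknown:
                        raise ValueError(
                            f"unknown {f.name} option(s): {sorted(unknown)}"
                        )
                    value = sub_cls(**value)
            kwargs[f.name] = value
        if data:
            raise ValueError(f"unknown config section(s): {sorted(data)}")
        cfg = cls(**kwargs)
        if isinstance(cfg.slides.canvas, list):
            cfg.slides.canvas = tuple(cfg.slides.canvas)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        import yaml

        data = self.to_dict()
        data["slides"]["canvas"] = list(data["slides"]["canvas"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _deg_criteria(options: SignatureOptions) -> signature_mod.DEGCriteria:
    presets = {
        "mouse": signature_mod.MOUSE_CRITERIA,
        "human": signature_mod.HUMAN_CRITERIA,
    }
    if options.species not in presets:
        raise ValueError(f"unknown species preset {options.species!r}")
    return presets[options.species]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def sample_cohort_metrics(
    opts: CountSimOptions, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample histology metrics for control and treated cohorts.

    Treated samples have thicker dermis, higher alignment and more collagen,
    mirroring the fibrotic shift the treated cohort shows over control.
    """
    n = opts.n_samples_per_group
    samples = [f"s{i:02d}" for i in range(2 * n)]
    groups = pd.Series(
        [opts.control_group] * n + [opts.treated_group] * n,
        index=samples,
        name="group",
    )
    thickness = np.concatenate(
        [rng.normal(40.0, 4.0, n), rng.normal(60.0, 6.0, n)]
    )
    alignment = np.clip(
        np.concatenate([rng.normal(0.62, 0.04, n), rng.normal(0.82, 0.04, n)]),
        0.5,
        0.98,
    )
    collagen = np.clip(
        np.concatenate([rng.normal(0.35, 0.05, n), rng.normal(0.55, 0.05, n)]),
        0.0,
        1.0,
    )
    metrics = pd.DataFrame(
        {"thickness": thickness, "alignment": alignment, "collagen": collagen},
        index=samples,
    )
    return metrics, groups


def build_signature_spec(opts: CountSimOptions) -> synthetic.SignatureSpec:
    slope = synthetic.slope_for_target_r2(
        opts.target_r2, opts.noise_sd, opts.baseline_mean, opts.dispersion
    )
    planted = {}
    for metric, count in opts.planted_per_metric.items():
        for i in range(count):
            planted[f"{metric[:5]}{i:03d}"] = (metric, slope, opts.noise_sd)
    return synthetic.SignatureSpec(
        n_genes=opts.n_genes,
        planted_genes=planted,
        baseline_mean=opts.baseline_mean,
        dispersion=opts.dispersion,
    )


def run_simulate(config: PipelineConfig) -> dict:
    """Emit slides, counts and trajectories with ground truth and a manifest."""
    out = Path(config.outdir) / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    logger.info("simulate: seeds=%s", config.seeds)
    # slides — one mixture spec per cohort, multiple slides each
    slides_dir = out / "slides"
    slides_dir.mkdir(exist_ok=True)
    slide_index = []
    slide_seed = int(config.seeds["slides"])
    so = config.slides
    k = 0
    for cohort, w in so.cohort_weights.items():
        for rep in range(so.n_slides_per_cohort):
            spec = synthetic.OrientationMixtureSpec(
                mu1=so.mu1, mu2=so.mu2, kappa=so.kappa, w=w
            )
            slide = synthetic.generate_slide(
                spec,
                n_bundles=so.n_bundles,
                canvas=tuple(so.canvas),
                seed=slide_seed + k,
            )
            prefix = slides_dir / f"slide_{cohort}_{rep}"
            paths = synthetic.write_slide(slide, prefix)
            files += [Path(p) for p in paths]
            slide_index.append(
                {
                    "slide": prefix.name,
                    "cohort": cohort,
                    "true_w": w,
                    "seed": slide_seed + k,
                    "n_bundles": so.n_bundles,
                }
            )
            k += 1
    index_path = slides_dir / "slide_index.csv"
    pd.DataFrame(slide_index).to_csv(index_path, index=False)
    files.append(index_path)

    # counts
    co = config.counts
    rng = np.random.default_rng(int(config.seeds["counts"]))
    metrics, groups = sample_cohort_metrics(co, rng)
    spec = build_signature_spec(co)
    matrix, truth, _ = synthetic.generate_counts(
        spec,
        metrics,
        groups,
        seed=int(config.seeds["counts"]) + 1,
        control_group=co.control_group,
    )
    counts_dir = out / "counts"
    paths = synthetic.write_counts(matrix, metrics, truth, counts_dir)
    files += [Path(p) for p in paths]

    # trajectories — aligned/random × control/knockdown siRNA
    to = config.trajectories
    frames = []
    tseed = int(config.seeds["trajectories"])
    for j, (substrate, sirna, kf) in enumerate(
        [
            ("aligned", to.control_sirna, 1.0),
            ("aligned", to.knockdown_sirna, to.knockdown_factor),
            ("random", to.control_sirna, 1.0),
            ("random", to.knockdown_sirna, 1.0),  # no effect on random fibers
        ]
    ):
        params = synthetic.TrajectoryParams(
            n_cells=to.n_cells,
            dt=to.dt,
            duration=to.duration,
            speed_mean=to.speed_mean,
            persistence=to.persistence,
            substrate=substrate,
            knockdown_factor=kf,
            well=f"w{j:02d}",
            condition=f"{substrate}:{sirna}",
        )
        df = synthetic.generate_trajectories(params, seed=tseed + j)
        df["cell_id"] = df["condition"] + "/" + df["cell_id"]
        frames.append(df)
    traj_path = out / "trajectories.csv"
    synthetic.write_trajectories(pd.concat(frames, ignore_index=True), traj_path)
    files.append(traj_path)

    manifest = {
        "seeds": config.seeds,
        "parameters": config.to_dict(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _load_slide_inputs(config: PipelineConfig):
    import tifffile

    out = Path(config.outdir) / "simulate" / "slides"
    index = pd.read_csv(out / "slide_index.csv")
    for _, row in index.iterrows():
        image = tifffile.imread(out / f"{row['slide']}.tif").astype(float) / 255.0
        epi = pd.read_csv(out / f"{row['slide']}_epidermis.csv")
        yield row, image, epi


def run_histology(config: PipelineConfig) -> pd.DataFrame:
    """Segment every slide and write bundle tables + partial metrics."""
    ho = config.histology
    logger.info("histology: %s", ho)
    out = Path(config.outdir) / "histology"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for row, image, epi in _load_slide_inputs(config):
        y_epi = epi["y"].to_numpy()
        ys = np.arange(image.shape[0])[:, None]
        dermis_mask = ys > y_epi[None, :]
        geom = histology_mod.extract_epidermis(dermis_mask, side="top")
        bundles = histology_mod.segment_bundles(
            image,
            min_area=ho.min_area,
            threshold=ho.threshold,
            opening_radius=ho.opening_radius,
        )
        rel = histology_mod.bundle_angles(bundles, geom, reference=ho.angle_reference)
        bundles["theta_rel_deg"] = rel
        bundles.to_csv(out / f"{row['slide']}_bundles.csv", index=False)
        stain = histology_mod.stain_mask(image, ho.threshold)
        rows.append(
            {
                "slide": row["slide"],
                "cohort": row["cohort"],
                "thickness": histology_mod.dermis_thickness(geom),
                "collagen_fraction": histology_mod.collagen_fraction(geom, stain),
                "n_bundles": len(bundles),
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "slide_metrics.csv", index=False)
    return metrics


def run_align(config: PipelineConfig) -> pd.DataFrame:
    """Fit the two-peak decomposition per slide and write scores + histogram plot."""
    ao = config.alignment
    logger.info("alignment: %s seed=%s", ao, config.seeds.get("alignment"))
    hist_dir = Path(config.outdir) / "histology"
    out = Path(config.outdir) / "alignment"
    out.mkdir(parents=True, exist_ok=True)
    index = pd.read_csv(
        Path(config.outdir) / "simulate" / "slides" / "slide_index.csv"
    )
    records = []
    for _, row in index.iterrows():
        bundles = pd.read_csv(hist_dir / f"{row['slide']}_bundles.csv")
        angles = bundles["theta_rel_deg"].to_numpy()
        if ao.method == "nearest_mode":
            score, modes = alignment_mod.nearest_mode_score(angles)
            rec = {"slide": row["slide"], "cohort": row["cohort"], "score": score,
                   "mu1": modes[0], "mu2": modes[1], "method": "nearest_mode"}
        else:
            decomp = alignment_mod.fit_two_peaks(
                angles,
                n_starts=ao.n_starts,
                tol=ao.tol,
                max_iter=ao.max_iter,
                seed=int(config.seeds.get("alignment", 0)),
                min_separation=ao.min_separation,
            )
            rec = {"slide": row["slide"], "cohort": row["cohort"],
                   "true_w": row.get("true_w"), **decomp.as_dict()}
        records.append(rec)
    table = pd.DataFrame(records)
    table.to_csv(out / "alignment_scores.csv", index=False)
    with open(out / "alignment_scores.json", "w") as fh:
        json.dump(records, fh, indent=2, default=float)
    _plot_angle_histograms(config, index, hist_dir, out)
    return table


def _plot_angle_histograms(config, index, hist_dir, out):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(index), figsize=(3.2 * len(index), 2.8), squeeze=False
    )
    for ax, (_, row) in zip(axes[0], index.iterrows()):
        bundles = pd.read_csv(hist_dir / f"{row['slide']}_bundles.csv")
        edges, dens = alignment_mod.angle_histogram(
            bundles["theta_rel_deg"].to_numpy(), bin_width=10.0
        )
        ax.bar(edges[:-1], dens, width=np.diff(edges), align="edge", color="#b33")
        ax.set_title(f"{row['cohort']}", fontsize=9)
        ax.set_xlabel("angle relative to epidermis (deg)")
        ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out / "angle_histograms.png", dpi=110)
    plt.close(fig)


def run_signature(config: PipelineConfig) -> dict:
    """DEG calling, metric correlation and signature intersection."""
    so = config.signature
    logger.info("signature: %s", so)
    counts_dir = Path(config.outdir) / "simulate" / "counts"
    out = Path(config.outdir) / "signature"
    out.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(counts_dir / "counts.tsv", sep="\t", index_col="gene")
    meta = pd.read_csv(counts_dir / "metrics.csv", index_col="sample")
    matrix = signature_mod.CountMatrix(counts=counts, groups=meta["group"])
    crit = _deg_criteria(so)

    norm, size_factors = signature_mod.normalize_counts(matrix)
    degs = signature_mod.call_degs_pooled(
        matrix, control_group=config.counts.control_group, crit=crit
    )
    degs.to_csv(out / "deg_table.csv", index_label="gene")

    expressed = norm.mean(axis=1) > crit.min_norm_count
    norm_expr = norm.loc[expressed]
    correlations = {
        metric: signature_mod.correlate_to_metric(
            norm_expr, meta[metric], scale=so.correlation_scale
        )
        for metric in so.r2_thresholds
    }
    signatures = signature_mod.build_signatures(
        correlations, degs["passed"].loc[expressed], thresholds=so.r2_thresholds
    )
    summary = {"n_degs": int(degs["passed"].sum()), "n_expressed": int(expressed.sum())}
    for metric, sig in signatures.items():
        (out / f"signature_{metric}.txt").write_text(
            "\n".join(sorted(sig.genes)) + ("\n" if sig.genes else "")
        )
        summary[metric] = {
            "n_genes": len(sig.genes),
            "n_unique": len(sig.unique_genes),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"summary": summary, "signatures": signatures, "degs": degs}


def run_migrate(config: PipelineConfig) -> dict:
    """Migration statistics, control normalization and knockdown comparisons."""
    mo = config.migration
    to = config.trajectories
    logger.info("migration: %s", mo)
    traj_path = Path(config.outdir) / "simulate" / "trajectories.csv"
    out = Path(config.outdir) / "migration"
    out.mkdir(parents=True, exist_ok=True)
    frames = pd.read_csv(traj_path)
    stats = migration_mod.compute_stats(frames, min_span_fraction=mo.min_span_fraction)
    stats.per_cell.to_csv(out / "per_cell_stats.csv", index=False)

    comparisons = {}
    tables = []
    for substrate in ("aligned", "random"):
        ctrl = f"{substrate}:{to.control_sirna}"
        kd = f"{substrate}:{to.knockdown_sirna}"
        sub = migration_mod.MigrationStats(
            per_cell=stats.per_cell[
                stats.per_cell["condition"].isin([ctrl, kd])
            ],
            per_group=stats.per_group[
                stats.per_group["condition"].isin([ctrl, kd])
            ],
            qc=stats.qc,
        )
        table = migration_mod.normalize_to_control(sub, control_label=ctrl)
        tables.append(table)
        comparisons[substrate] = migration_mod.compare_conditions(
            sub, ctrl, kd, test=mo.test
        )
    per_group = pd.concat(tables, ignore_index=True)
    per_group.to_csv(out / "per_group_summary.csv", index=False)
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=2)
    return {"per_group": per_group, "comparisons": comparisons, "qc": stats.qc}


def run_full(config: PipelineConfig) -> dict:
    """Run every stage in order and aggregate one JSON report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}
    stages = [
        ("simulate", run_simulate),
        ("histology", run_histology),
        ("alignment", run_align),
        ("signature", run_signature),
        ("migration", run_migrate),
    ]
    for name, fn in stages:
        logger.info("stage %s starting", name)
        try:
            result = fn(config)
        except Exception as exc:  # noqa: BLE001 — named-stage failure contract
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if name == "histology":
            report["histology"] = result.to_dict(orient="records")
        elif name == "alignment":
            report["alignment"] = result.to_dict(orient="records")
        elif name == "signature":
            report["signature"] = result["summary"]
        elif name == "migration":
            report["migration"] = {
                "per_group": result["per_group"].to_dict(orient="records"),
                "comparisons": result["comparisons"],
            }
        else:
            report["simulate"] = {"n_files": len(result["files"])}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
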