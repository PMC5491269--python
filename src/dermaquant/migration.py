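"""Time-lapse fibroblast migration statistics.

Per-cell metrics from tracked positions: net displacement (straight-line
start-to-end distance), accumulated distance (path length) and
directionality (their ratio; 1 = ballistic, 0 = closed loop). Group
summaries average over cells, and mean displacement can be normalized to a
control condition to express siRNA knockdown effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

__all__ = [
    "MigrationStats",
    "compute_stats",
    "normalize_to_control",
    "compare_conditions",
]

REQUIRED_COLUMNS = ("cell_id", "t_min", "x_px", "y_px")


@dataclass
class MigrationStats:
    """Per-cell and per-condition migration summaries.

    ``per_cell`` columns: cell_id, condition, well, n_points,
    net_displacement, accumulated_distance, directionality.
    ``per_group`` columns: condition, n_cells, mean_displacement,
    mean_accumulated, mean_directionality. ``qc`` records excluded tracks.
    """

    per_cell: pd.DataFrame
    per_group: pd.DataFrame
    qc: dict


def compute_stats(frames: pd.DataFrame, min_span_fraction: float = 0.5) -> MigrationStats:
    """Compute migration statistics from a long-format trajectory table.

    Cells whose tracked time span covers less than ``min_span_fraction`` of
    the movie (or with < 2 points) are excluded and counted in the QC
    report; timestamps must be strictly increasing within each cell.
    """
    if frames is None or len(frames) == 0:
        raise ValueError("empty trajectory table")
    missing = [c for c in REQUIRED_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    frames = frames.sort_values(["cell_id", "t_min"], kind="stable")
    movie_span = float(frames["t_min"].max() - frames["t_min"].min())

    keys = [c for c in ("condition", "well", "cell_id") if c in frames.columns]
    rows, excluded = [], 0
    for key, track in frames.groupby(keys, sort=False):
        cell_id = key[-1] if isinstance(key, tuple) else key
        t = track["t_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"timestamps not strictly increasing for cell {cell_id!r}")
        span = t[-1] - t[0]
        if len(t) < 2 or (movie_span > 0 and span < min_span_fraction * movie_span):
            excluded += 1
            continue
        xy = track[["x_px", "y_px"]].to_numpy(dtype=float)
        steps = np.hypot(*np.diff(xy, axis=0).T)
        accumulated = float(steps.sum())
        net = float(np.hypot(*(xy[-1] - xy[0])))
        rows.append(
            (
                cell_id,
                track["condition"].iloc[0] if "condition" in track else "all",
                track["well"].iloc[0] if "well" in track else "w00",
                len(t),
                net,
                accumulated,
                net / accumulated if accumulated > 0 else 0.0,
            )
        )
    if not rows:
        raise ValueError("no track passed the length filter")
    per_cell = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "condition",
            "well",
            "n_points",
            "net_displacement",
            "accumulated_distance",
            "directionality",
        ],
    )
    per_group = (
        per_cell.groupby("condition")
        .agg(
            n_cells=("cell_id", "size"),
            mean_displacement=("net_displacement", "mean"),
            mean_accumulated=("accumulated_distance", "mean"),
            mean_directionality=("directionality", "mean"),
        )
        .reset_index()
    )
    return MigrationStats(
        per_cell=per_cell,
        per_group=per_group,
        qc={"n_excluded": excluded, "n_kept": len(per_cell)},
    )


def normalize_to_control(stats: MigrationStats, control_label: str) -> pd.DataFrame:
    """Divide each condition's mean displacement by the control's.

    Returns the per-group table with a ``normalized_mean_displacement``
    column; the control condition maps to 1.0.
    """
    table = stats.per_group
    ctrl = table.loc[table["condition"] == control_label, "mean_displacement"]
    if ctrl.empty:
        raise ValueError(f"control condition {control_label!r} not present")
    out = table.copy()
    out["normalized_mean_displacement"] = out["mean_displacement"] / float(
        ctrl.iloc[0]
    )
    return out


def compare_conditions(
    stats: MigrationStats,
    group_a: str,
    group_b: str,
    test: str = "welch",
    metric: str = "net_displacement",
) -> dict:
    """Effect ratio and p-value for one per-cell metric between two groups.

    Default test is Welch's two-sample t on per-cell net displacement;
    ``test="mannwhitney"`` switches to the rank test. The effect ratio is
    mean(B) / mean(A).
    """
    per_cell = stats.per_cell
    a = per_cell.loc[per_cell["condition"] == group_a, metric].to_numpy(dtype=float)
    b = per_cell.loc[per_cell["condition"] == group_b, metric].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 cells per group")
    if test == "welch":
        p = float(stats_ttest(a, b))
    elif test == "mannwhitney":
        p = float(scipy_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "ratio": float(b.mean() / a.mean()) if a.mean() != 0 else float("inf"),
        "p_value": p,
        "test": test,
        "metric": metric,
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }


def stats_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value; identical samples map to p = 1."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = scipy_stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if not np.isfinite(p) else float(p)
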