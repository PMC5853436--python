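"""Figure output: overlays, correlation panel, heat maps, densities, ellipses.

Plots are best-effort artifacts for inspection; the numeric CSV/JSON
outputs are the pipeline's contract.  All functions return the saved path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse
from scipy.stats import gaussian_kde

from .discrim import ConfidenceEllipse, GroupDistanceMap
from .rootgen import HIGH_NUPE_LINES, LOW_NUPE_LINES, RootSystem
from .select_resample import PermutationResult

#: Group colour convention: 0 black, 1 magenta, 2 green, 3 blue.
GROUP_COLORS = {0: "black", 1: "magenta", 2: "green", 3: "blue"}


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def overlay_plot(cohort: list[RootSystem], path: str | Path) -> Path:
    """Overlay all plants per line x nitrate cell, 4-row layout.

    Rows: low-NUpE/low-N, low-NUpE/high-N, high-NUpE/low-N, high-NUpE/high-N;
    each line keeps its column between its two rows.  Absent cells render
    blank.
    """
    if not cohort:
        raise ValueError("empty cohort")
    lines_low = [l for l in LOW_NUPE_LINES if any(s.meta.line == l for s in cohort)]
    lines_high = [l for l in HIGH_NUPE_LINES if any(s.meta.line == l for s in cohort)]
    extra = sorted({s.meta.line for s in cohort} - set(lines_low) - set(lines_high))
    for l in extra:
        (lines_low if any(s.meta.line == l and s.meta.nupe_class == "low" for s in cohort)
         else lines_high).append(l)
    ncols = max(len(lines_low), len(lines_high), 1)
    fig, axes = plt.subplots(4, ncols, figsize=(2.0 * ncols, 8.0), squeeze=False)
    rows = [("low", "low", lines_low), ("low", "high", lines_low),
            ("high", "low", lines_high), ("high", "high", lines_high)]
    for r, (nupe, nitrate, lines) in enumerate(rows):
        for c in range(ncols):
            ax = axes[r][c]
            ax.set_xticks([])
            ax.set_yticks([])
            if c >= len(lines):
                ax.axis("off")
                continue
            line = lines[c]
            plants = [s for s in cohort
                      if s.meta.line == line and s.meta.nupe_class == nupe
                      and s.meta.nitrate == nitrate]
            if not plants:
                continue
            color = GROUP_COLORS[plants[0].meta.group_code]
            for s in plants:
                for cv in s.curves:
                    pts = cv.points - s.seed_point
                    ax.plot(pts[:, 0], pts[:, 1], color=color, lw=0.4, alpha=0.6)
            ax.invert_yaxis()
            ax.set_title(f"{line} {'N+' if nitrate == 'high' else 'N-'}", fontsize=8)
    fig.tight_layout()
    return _save(fig, path)


def correlation_panel(corr, keep: list[str], path: str | Path) -> Path:
    """Heat map of the correlations among the retained variables."""
    sub = corr.loc[keep, keep]
    fig, ax = plt.subplots(figsize=(0.6 * len(keep) + 2, 0.6 * len(keep) + 2))
    im = ax.imshow(sub.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(keep)), keep, rotation=90, fontsize=7)
    ax.set_yticks(range(len(keep)), keep, fontsize=7)
    for i in range(len(keep)):
        for j in range(len(keep)):
            ax.text(j, i, f"{sub.iloc[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return _save(fig, path)


def distance_heatmap(gmap: GroupDistanceMap, path: str | Path) -> Path:
    """Mahalanobis group-distance heat map (darker = closer)."""
    n = len(gmap.labels)
    fig, ax = plt.subplots(figsize=(0.45 * n + 2, 0.45 * n + 2))
    im = ax.imshow(gmap.values, cmap="gray")
    ax.set_xticks(range(n), gmap.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), gmap.labels, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Mahalanobis distance")
    ax.set_title(f"ordering: {gmap.ordering}", fontsize=9)
    fig.tight_layout()
    return _save(fig, path)


def score_density_plot(scores: np.ndarray, group_codes, path: str | Path,
                       labels=("LD1", "LD2", "LD3")) -> Path:
    """Gaussian-KDE densities of discriminant scores per group."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == len(np.asarray(group_codes)):
        scores = scores.T  # rows become discriminants
    r = scores.shape[0]
    codes = np.asarray(group_codes)
    fig, axes = plt.subplots(1, r, figsize=(4 * r, 3), squeeze=False)
    for j in range(r):
        ax = axes[0][j]
        for g in np.unique(codes):
            v = scores[j][codes == g]
            if len(v) < 2 or np.std(v) == 0:
                continue
            kde = gaussian_kde(v)  # Silverman-style default bandwidth
            xs = np.linspace(v.min() - 1, v.max() + 1, 200)
            ax.plot(xs, kde(xs), color=GROUP_COLORS.get(int(g), "gray"), label=str(g))
        ax.set_xlabel(labels[j] if j < len(labels) else f"LD{j + 1}")
        ax.legend(fontsize=7, title="group")
    fig.tight_layout()
    return _save(fig, path)


def loadings_plot(loadings_frame, path: str | Path) -> Path:
    """Bar chart of the loadings of each discriminant."""
    r = loadings_frame.shape[1]
    fig, axes = plt.subplots(1, r, figsize=(4 * r, 3.5), squeeze=False)
    for j, col in enumerate(loadings_frame.columns):
        ax = axes[0][j]
        ax.bar(range(len(loadings_frame)), loadings_frame[col].to_numpy())
        ax.set_xticks(range(len(loadings_frame)), loadings_frame.index,
                      rotation=90, fontsize=6)
        ax.set_title(col)
        ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    return _save(fig, path)


def confidence_region_plot(ellipses: list[ConfidenceEllipse], path: str | Path,
                           dims=("LD1", "LD2")) -> Path:
    """Group mean scores with their confidence ellipses."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for e in ellipses:
        color = GROUP_COLORS.get(int(e.group) if str(e.group).isdigit() else -1, "gray")
        ax.plot(*e.center, "o", color=color, label=str(e.group))
        ax.add_patch(Ellipse(e.center, 2 * e.semi_axes[0], 2 * e.semi_axes[1],
                             angle=e.angle_deg, fill=False, color=color))
    ax.set_xlabel(dims[0])
    ax.set_ylabel(dims[1])
    ax.legend(fontsize=7, title="group")
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    return _save(fig, path)


def permutation_histograms(results: list[PermutationResult], path: str | Path) -> Path:
    """Null histograms with the observed statistic marked, one panel per scheme."""
    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3), squeeze=False)
    for j, res in enumerate(results):
        ax = axes[0][j]
        ax.hist(res.null_statistics, bins=40, color="steelblue")
        ax.axvline(res.observed, color="red")
        ax.set_title(f"{res.scheme}\nP={res.p_value:.4g}", fontsize=8)
        ax.set_xlabel("zeta^2")
    fig.tight_layout()
    return _save(fig, path)


def exemplar_strip(exemplars, cohort: list[RootSystem], path: str | Path) -> Path:
    """Plants nearest each LD1 percentile, drawn left to right."""
    by_id = {s.plant_id: s for s in cohort}
    fig, ax = plt.subplots(figsize=(1.4 * len(exemplars), 6))
    qvals = [qv for _, qv, _ in exemplars]
    span = (max(qvals) - min(qvals)) or 1.0
    for col, (q, qv, ids) in enumerate(exemplars):
        for row, pid in enumerate(ids):
            s = by_id[pid]
            pts_all = np.vstack([c.points for c in s.curves]) - s.seed_point
            scale = 0.6 / max(np.abs(pts_all).max(), 1e-9)
            for c in s.curves:
                pts = (c.points - s.seed_point) * scale
                ax.plot(col + pts[:, 0], row + pts[:, 1],
                        color=GROUP_COLORS[s.meta.group_code], lw=0.4)
    ax.plot(range(len(exemplars)),
            [len(exemplars[0][2]) + 0.5 + (qv - min(qvals)) / span for qv in qvals],
            "r--", label="LD1 percentile")
    ax.set_xticks(range(len(exemplars)), [f"{q:.1f}" for q, _, _ in exemplars])
    ax.set_xlabel("LD1 percentile")
    ax.set_yticks([])
    ax.invert_yaxis()
    fig.tight_layout()
    return _save(fig, path)
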