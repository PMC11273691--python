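"""Publication figure rendering for clustering and DE QC outputs.

Each function takes already-computed plot data (the corresponding TSV is
written by the CLI alongside the figure) and renders a PNG/SVG with
matplotlib. Rendering is deliberately separated from computation so tests
exercise the data layer without touching a display backend.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .auto_clustering import HeatmapData
from .viz_stats import PCAResult

_VOLCANO_COLORS = {"up": "#d62728", "down": "#1f77b4", "ns": "#bbbbbb"}


def save_heatmap(data: HeatmapData, path: str | Path, cmap: str = "viridis") -> None:
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(data.values, aspect="auto", interpolation="nearest", cmap=cmap)
    for b in data.boundaries[:-1]:
        ax.axhline(b - 0.5, color="white", linewidth=1.2)
    ax.set_xlabel("sample")
    ax.set_ylabel("feature (cluster-ordered)")
    fig.colorbar(im, ax=ax, label="signal")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_embedding(
    coords: np.ndarray, labels: np.ndarray, path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    scatter = ax.scatter(
        coords[:, 0], coords[:, 1], c=labels, s=12, cmap="tab10", linewidths=0
    )
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.colorbar(scatter, ax=ax, label="cluster")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_silhouette_curve(silhouette_by_k: dict[int, float], path: str | Path) -> None:
    ks = sorted(silhouette_by_k)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ks, [silhouette_by_k[k] for k in ks], marker="o")
    best = max(ks, key=lambda k: (silhouette_by_k[k], -k))
    ax.axvline(best, color="grey", linestyle=":")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("mean silhouette")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_pca(result: PCAResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    xs, ys = result.coordinates[:, 0], result.coordinates[:, 1]
    ax.scatter(xs, ys, s=40)
    for sid, x, y in zip(result.sample_ids, xs, ys):
        ax.annotate(sid, (x, y), fontsize=8, xytext=(3, 3), textcoords="offset points")
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0] * 100:.1f}% variance)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({ve[1] * 100:.1f}% variance)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_volcano(
    table: pd.DataFrame, labels: pd.Series, lfc_cut: float, padj_cut: float,
    path: str | Path,
) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    neg_log_p = -np.log10(table["padj"].fillna(1.0).clip(lower=1e-300))
    for cls, color in _VOLCANO_COLORS.items():
        mask = labels == cls
        ax.scatter(
            table.loc[mask, "log2FoldChange"], neg_log_p[mask],
            s=8, c=color, label=cls, linewidths=0,
        )
    ax.axvline(lfc_cut, linestyle=":", color="grey")
    ax.axvline(-lfc_cut, linestyle=":", color="grey")
    ax.axhline(-np.log10(padj_cut), linestyle=":", color="grey")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p-value")
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_ma(points: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    sig = points["significant"]
    ax.scatter(points.loc[~sig, "A"], points.loc[~sig, "M"], s=8, c="#bbbbbb",
               label="ns", linewidths=0)
    ax.scatter(points.loc[sig, "A"], points.loc[sig, "M"], s=8, c="#d62728",
               label="significant", linewidths=0)
    ax.axhline(0, color="grey", linewidth=0.8)
    ax.set_xlabel("log10(mean expression + 1)")
    ax.set_ylabel("log2 fold change")
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
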