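"""Thin matplotlib renderers over the plot-data builders.

Each renderer is a pure function of its plot-data argument and writes a
PNG or SVG (chosen by extension). Styling is deliberately minimal; the
plot-data builders carry the semantics and are what the tests exercise.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .compare import OverlapMatrices, overlap_heatmap_data
from .summarize import ChordData, CompositionTable

__all__ = ["render_pie", "render_bar", "render_heatmap", "render_bubble", "render_chord"]


def _save(fig, path: str | Path) -> None:
    path = Path(path)
    try:
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    finally:
        plt.close(fig)


def render_pie(comp: CompositionTable, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    t = comp.table
    ax.pie(t["count"], labels=[f"{l} ({p:.2f}%)" for l, p in zip(t["label"], t["percent"])])
    ax.set_title(title)
    _save(fig, path)


def render_bar(comp: CompositionTable, path: str | Path, top: int | None = None, title: str = "") -> None:
    t = comp.table if top is None else comp.table.head(top)
    fig, ax = plt.subplots(figsize=(8, max(2, 0.4 * len(t))))
    ax.barh(t["label"][::-1], t["percent"][::-1])
    ax.set_xlabel("percent of unique records")
    ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)


def render_heatmap(m: OverlapMatrices, path: str | Path, title: str = "") -> None:
    grid = overlap_heatmap_data(m)
    n = len(grid["labels"])
    fig, ax = plt.subplots(figsize=(1.5 * n + 2, 1.2 * n + 1))
    im = ax.imshow(grid["fill"], cmap="Reds", vmin=0, vmax=100)
    ax.set_xticks(range(n), grid["labels"], rotation=45, ha="right")
    ax.set_yticks(range(n), grid["labels"])
    for i in range(n):
        for j in range(n):
            ax.text(j, i, grid["text"][i, j], ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="% shared (of row group)")
    ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)


def render_bubble(bubble: "pd.DataFrame", path: str | Path, title: str = "") -> None:
    """Enrichment bubble plot: x = richness, area ∝ k, color = -log10 p."""
    fig, ax = plt.subplots(figsize=(7, max(3, 0.5 * len(bubble))))
    y = np.arange(len(bubble))[::-1]
    sc = ax.scatter(
        bubble["richness"],
        y,
        s=40.0 * bubble["size"].to_numpy(dtype=float),  # area linear in k
        c=bubble["neg_log10_p"],
        cmap="Reds",
        edgecolor="black",
        linewidth=0.5,
    )
    ax.set_yticks(y, bubble["label"])
    ax.set_xlabel("richness factor (k / K)")
    fig.colorbar(sc, ax=ax, label="-log10 p")
    ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)


def render_chord(data: ChordData, path: str | Path, title: str = "") -> None:
    """Circular chord-style diagram linking the two label sets.

    Labels are placed on a circle (left set on one half, right set on the
    other); each positive-weight pair is drawn as a quadratic Bezier through
    the center with line width proportional to weight.
    """
    labels = list(data.left) + list(data.right)
    n = len(labels)
    theta = {
        lab: np.pi / 2 + 2 * np.pi * i / n for i, lab in enumerate(labels)
    }
    pos = {lab: (np.cos(t), np.sin(t)) for lab, t in theta.items()}
    wmax = max(1, data.weights["weight"].max())

    fig, ax = plt.subplots(figsize=(7, 7))
    for _, row in data.weights.iterrows():
        x0, y0 = pos[str(row["x"])]
        x1, y1 = pos[str(row["y"])]
        t = np.linspace(0, 1, 50)[:, None]
        curve = ((1 - t) ** 2) * np.array([x0, y0]) + 2 * t * (1 - t) * np.array([0.0, 0.0]) + (t**2) * np.array([x1, y1])
        ax.plot(curve[:, 0], curve[:, 1], lw=0.5 + 3.0 * row["weight"] / wmax, alpha=0.6)
    for lab, (x, y) in pos.items():
        ha = "left" if x >= 0 else "right"
        ax.text(1.05 * x, 1.05 * y, str(lab), ha=ha, va="center", fontsize=8)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    _save(fig, path)
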