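"""Figure generation for a pipeline bundle.

Renders the interlayer overlap heatmap, the JSD heatmap with its Ward
dendrogram, the reducibility relative-entropy curve and a centrality rank
table per group.  Every value drawn here is read from the bundle the
pipeline already wrote to disk; plotting failures degrade to warnings so a
headless or font-less environment never loses the data artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram, linkage

log = logging.getLogger("primatenet")

__all__ = ["plot_reports"]

_SHORT = {
    "stationary_vicinity": "SV",
    "affiliative": "AFF",
    "grooming": "GRM",
    "passive_close_proximity": "PCP",
    "aggregate": "AGG",
    "multiplex": "MUX",
}


def _heatmap(ax, matrix: np.ndarray, labels: list[str], title: str, cmap: str) -> None:
    masked = np.ma.masked_invalid(matrix)
    im = ax.imshow(masked, cmap=cmap, vmin=0)
    ax.set_xticks(range(len(labels)), [_SHORT.get(l, l) for l in labels], rotation=45)
    ax.set_yticks(range(len(labels)), [_SHORT.get(l, l) for l in labels])
    for i in range(len(labels)):
        for j in range(len(labels)):
            txt = "n/a" if np.ma.is_masked(masked[i, j]) else f"{matrix[i, j]:.2f}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    ax.set_title(title)
    plt.colorbar(im, ax=ax, fraction=0.046)


def plot_reports(bundle: dict[str, Any], outdir: str | Path) -> list[Path]:
    """Render the bundle's figures into ``outdir``/figures; returns paths."""
    outdir = Path(outdir) / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for group, g in bundle["groups"].items():
        layer_names = list(g["network"].layer_names)
        try:
            fig, ax = plt.subplots(figsize=(4.5, 4))
            _heatmap(ax, g["overlap"], layer_names, f"edge overlap — {group}", "Greens")
            fig.tight_layout()
            p = outdir / f"overlap_{group}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover - rendering environment
            log.warning("overlap heatmap for %s failed: %s", group, exc)

        try:
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            _heatmap(ax1, g["jsd"], layer_names, f"quantum JSD — {group}", "Purples")
            if not np.isnan(g["jsd"]).any():
                links = linkage(g["jsd"][np.triu_indices(len(layer_names), k=1)],
                                method="ward")
                dendrogram(links, labels=[_SHORT.get(l, l) for l in layer_names], ax=ax2)
                ax2.set_title("Ward clustering of layers")
            fig.tight_layout()
            p = outdir / f"jsd_{group}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover
            log.warning("JSD figure for %s failed: %s", group, exc)

        try:
            red = g["reducibility"]
            if red is not None:
                curve = red.relative_entropy_curve
                xs = list(range(len(curve), 0, -1))
                fig, ax = plt.subplots(figsize=(4.5, 3.2))
                ax.plot(xs, curve, "o-")
                ax.set_xlabel("number of layers")
                ax.set_ylabel("relative entropy")
                ax.set_title(f"reducibility — {group}")
                ax.invert_xaxis()
                fig.tight_layout()
                p = outdir / f"reducibility_{group}.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
        except Exception as exc:  # pragma: no cover
            log.warning("reducibility curve for %s failed: %s", group, exc)

        try:
            report = g["centrality"]
            ranks = report.ranks[report.ring_order]
            fig, ax = plt.subplots(figsize=(5.5, 3.2))
            ax.axis("off")
            cells = [[str(v) for v in row] for row in ranks.values]
            table = ax.table(
                cellText=cells,
                rowLabels=list(ranks.index),
                colLabels=[_SHORT.get(c, c) for c in ranks.columns],
                loc="center",
            )
            table.scale(1, 1.2)
            ax.set_title(f"eigenvector ranks per ring — {group}")
            fig.tight_layout()
            p = outdir / f"ranks_{group}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover
            log.warning("rank table for %s failed: %s", group, exc)
    return written
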