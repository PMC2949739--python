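"""Optional figures: decay scatter + fitted curve, and the r² grid raster."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ld_decay import DecayFit
from .ld_pairwise import LDGrid, PairwiseLD


def decay_plot(
    pairs_by_label: dict[str, list[PairwiseLD]],
    fits_by_label: dict[str, DecayFit] | None = None,
    path: str | None = None,
    title: str = "",
):
    """r² versus inter-site distance, one color per dataset label."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, pairs in pairs_by_label.items():
        ax.scatter(
            [p.distance for p in pairs], [p.r2 for p in pairs],
            s=8, alpha=0.5, label=label,
        )
        if fits_by_label and label in fits_by_label:
            fit = fits_by_label[label]
            ax.plot(fit.grid, fit.curve, lw=1.5)
    ax.set_xlabel("distance (bases)")
    ax.set_ylabel(r"$r^2$")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def grid_plot(grid: LDGrid, path: str | None = None, title: str = ""):
    """Lower-triangle r² grid, white (r²=0) to black (r²=1)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(grid.matrix, cmap="Greys", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xticks(range(len(grid.site_columns)))
    ax.set_xticklabels(grid.site_columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(grid.site_columns)))
    ax.set_yticklabels(grid.site_columns, fontsize=5)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
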