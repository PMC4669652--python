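"""Basic figure rendering: co-localization heat map and TSS-distance bars.

PNG output is a convenience view of the TSV reports, not a primary artifact;
the pipeline only writes figures when asked to (``render_png: true``).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coloc import HeatmapMatrix


def render_heatmap(hm: HeatmapMatrix, path: str, title: str = "signal at anchors") -> None:
    """Anchor x position heat map, rows already ordered by descending total."""
    fig, ax = plt.subplots(figsize=(4, 6))
    vmax = np.percentile(hm.values, 99) or 1.0
    ax.imshow(
        hm.values, aspect="auto", interpolation="nearest",
        cmap="Reds", vmin=0, vmax=max(vmax, 1e-9),
    )
    ax.set_xlabel(f"position (+/- {hm.flank} bp, {hm.n_bins} bins)")
    ax.set_ylabel("anchor peaks")
    ax.set_yticks([])
    ax.set_title(title)
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def render_tss_histogram(frame: pd.DataFrame, path: str) -> None:
    """Bar chart of the TSS-distance histogram table."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(frame)), frame["count"])
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame["bin"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("peaks")
    ax.set_xlabel("distance from peak center to nearest TSS")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
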