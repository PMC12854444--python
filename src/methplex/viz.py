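"""Plots for cohort reports: blank-count dot plots and ctDNA fraction stacks."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .lob import LobTable, SampleCall
from .panel import DEFAULT_PANEL, Panel

MARKER_COLORS = {
    "ACTRT2": "#3b6fb5",
    "EVX1": "#3fa24c",
    "HOXD13": "#8a8a8a",
    "DOCK2": "#e4c23a",
    "HAPLN3": "#e07b2a",
}


def lob_dot_plot(
    blank_counts: Mapping[str, Sequence[int]],
    lob: LobTable,
    path: str | Path,
    panel: Panel = DEFAULT_PANEL,
) -> None:
    """Per-assay blank positive-droplet dot plot with the LOB dashed line."""
    markers = [m for m in panel.markers if m in blank_counts]
    fig, axes = plt.subplots(1, len(markers), figsize=(2.2 * len(markers), 3.2),
                             sharey=False)
    if len(markers) == 1:
        axes = [axes]
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for ax, marker in zip(axes, markers):
        counts = np.asarray(list(blank_counts[marker]))
        x = rng.uniform(-0.15, 0.15, size=counts.size)
        ax.plot(x, counts, "o", ms=4, alpha=0.6,
                color=MARKER_COLORS.get(marker, "k"))
        ax.axhline(lob[marker], ls="--", color="k", lw=1)
        ax.set_title(marker, fontsize=9, style="italic")
        ax.set_xticks([])
        ax.set_ylim(bottom=-0.5)
    axes[0].set_ylabel("positive droplets")
    fig.suptitle("Blank cohort positive droplets (dashed = LOB)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fraction_stack_plot(
    calls: Sequence[SampleCall],
    path: str | Path,
    panel: Panel = DEFAULT_PANEL,
) -> None:
    """Stacked per-sample ctDNA fractions (marker/ALB x 100) per marker."""
    samples = [c.sample_id for c in calls]
    x = np.arange(len(samples))
    fig, ax = plt.subplots(figsize=(max(4.0, 0.45 * len(samples)), 3.6))
    bottom = np.zeros(len(samples))
    for marker in panel.markers:
        vals = np.array(
            [c.ctdna_fraction_pct.get(marker) or 0.0 for c in calls], dtype=float
        )
        ax.bar(x, vals, bottom=bottom, width=0.7, label=marker,
               color=MARKER_COLORS.get(marker, "k"))
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(samples, rotation=90, fontsize=7)
    ax.set_ylabel("ctDNA fraction (% of ALB), stacked")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
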