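"""Figures: sensory-weight surfaces over the stimulus grid."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_weight_surface"]


def plot_weight_surface(
    surface: pd.DataFrame,
    target: str = "auditory",
    path: str | Path | None = None,
):
    """Heatmap of the cross-modal weight per (auditory x visual) pair.

    For an auditory target the plotted quantity is w_V — the visual
    cue's pull on the auditory distance estimate; cells above 0.5 form
    the interaction window of each row.
    """
    cross = "w_V" if target == "auditory" else "w_A"
    grid = surface.pivot(
        index="auditory_distance", columns="visual_distance", values=cross
    ).sort_index()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        grid.to_numpy(),
        origin="lower",
        aspect="auto",
        vmin=0.0,
        vmax=1.0,
        cmap="viridis",
        extent=(
            grid.columns.min() - 1,
            grid.columns.max() + 1,
            grid.index.min() - 0.5,
            grid.index.max() + 0.5,
        ),
    )
    ax.set_xlabel("visual stimulus distance (m)")
    ax.set_ylabel("auditory stimulus distance (m)")
    label = "visual weight on auditory estimate" if target == "auditory" else "auditory weight on visual estimate"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"Sensory weights ({target} estimates)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
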