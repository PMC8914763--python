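"""Optional visualization helpers (debug output only, never re-imported)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import Thermogram
from .symmetry import AxisLine, Hull


def save_thermogram_png(tg: Thermogram, path: str | Path, cmap: str = "inferno") -> None:
    """Render the temperature grid to a PNG with a °C colorbar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(tg.values, cmap=cmap)
    fig.colorbar(im, ax=ax, label="°C")
    ax.set_title(f"{tg.id} ({tg.view})")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_axis_overlay_png(
    tg: Thermogram, hull: Hull, axis: AxisLine, path: str | Path
) -> None:
    """Thermogram with the hull polygon and symmetry axis drawn over it."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(tg.values, cmap="inferno")
    fig.colorbar(im, ax=ax, label="°C")
    verts = np.vstack([hull.vertices, hull.vertices[:1]])
    ax.plot(verts[:, 1], verts[:, 0], "c-", lw=1.5, label="convex hull")
    pr, pc = axis.point
    dr, dc = axis.direction
    half = max(tg.n_rows, tg.n_cols)
    ax.plot(
        [pc - half * dc, pc + half * dc],
        [pr - half * dr, pr + half * dr],
        "w--", lw=1.5, label="symmetry axis",
    )
    ax.set_xlim(0, tg.n_cols - 1)
    ax.set_ylim(tg.n_rows - 1, 0)
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_roc_png(roc_points: np.ndarray, auc: float, path: str | Path) -> None:
    """Plot the pooled ROC curve with its area in the legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc_points[:, 0], roc_points[:, 1], "b-", label=f"AUC = {auc:.4f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
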