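"""False-colour rendering of densitograms.

The colour scale follows the printed convention: the 200–1200 HU range is
divided into ten 100-HU classes with dedicated under/over colours, so two
renderings are directly comparable regardless of the HU range each joint
actually spans.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm

from .projection import Densitogram

__all__ = ["save_densitogram_png", "false_colour_norm"]

FALSE_COLOUR_RANGE_HU = (200.0, 1200.0)
N_COLOUR_CLASSES = 10


def false_colour_norm():
    """(cmap, norm) implementing the 10-class 200–1200 HU scale."""
    bounds = np.linspace(*FALSE_COLOUR_RANGE_HU, N_COLOUR_CLASSES + 1)
    cmap = plt.get_cmap("turbo", N_COLOUR_CLASSES).copy()
    cmap.set_under("black")
    cmap.set_over("white")
    cmap.set_bad("0.85")
    return cmap, BoundaryNorm(bounds, N_COLOUR_CLASSES)


def save_densitogram_png(dg: Densitogram, path: str | Path, dpi: int = 120) -> Path:
    """Render a densitogram to PNG with the false-colour scale and a colourbar."""
    cmap, norm = false_colour_norm()
    img = np.where(dg.surface_mask, dg.values_hu, np.nan)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(img, cmap=cmap, norm=norm, origin="upper", interpolation="nearest")
    label = f"{dg.subject_id or ''} {dg.timepoint or ''} {dg.view_name}".strip()
    ax.set_title(label or dg.view_name)
    ax.set_xlabel("column (x)")
    ax.set_ylabel("row (y)")
    fig.colorbar(im, ax=ax, extend="both", label="HU")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
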