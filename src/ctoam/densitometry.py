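"""Densitogram quantization, density-maximum detection and the MAR statistic.

Quantization maps HU onto 8-bit levels over a fixed window (default
200–1200 HU, the same range the false-colour scale spans) and splits the
256 levels equally over 8 bins of 32 levels each.  A *density maximum* is a
connected region of pixels whose values fall in the two highest bins
(bin ≥ 7).  Maxima are localized on a fixed 30 × 30 unit grid spanned by
the bounding box of the joint surface, which normalizes coordinates across
joints of different sizes, and summarized by the maximum area ratio

    MAR = (pixels of the density maximum) / (pixels of the joint surface),

a size-independent fraction (also reported ×100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import ConfigError, FrameError, InputError
from .projection import Densitogram

__all__ = [
    "QuantizedDensitogram",
    "MaximumRegion",
    "GridFrame",
    "MarResult",
    "quantize",
    "detect_maxima",
    "to_grid",
    "compute_mar",
    "DEFAULT_WINDOW_HU",
    "N_BINS",
    "LEVELS_PER_BIN",
    "TOP_BIN_THRESHOLD",
]

DEFAULT_WINDOW_HU = (200.0, 1200.0)
N_BINS = 8
LEVELS_PER_BIN = 256 // N_BINS  # 32
TOP_BIN_THRESHOLD = N_BINS - 1  # bins 7 and 8 define a density maximum


def level_to_bin(level):
    """Map 8-bit levels (0–255) to bins 1–8; 32 levels per bin, 255 → bin 8."""
    level = np.asarray(level)
    return np.minimum(level // LEVELS_PER_BIN, N_BINS - 1) + 1


@dataclass
class QuantizedDensitogram:
    """8-bit quantization of a densitogram.

    ``levels`` holds values 0–255 on surface pixels and −1 elsewhere;
    ``bins`` holds 1–8 on surface pixels and 0 elsewhere.
    """

    levels: np.ndarray
    bins: np.ndarray
    window: tuple[float, float]
    source: Densitogram = field(repr=False)

    @property
    def surface_mask(self) -> np.ndarray:
        return self.source.surface_mask


def quantize(dg: Densitogram, window: tuple[float, float] = DEFAULT_WINDOW_HU) -> QuantizedDensitogram:
    """Quantize a densitogram's HU values to 8-bit levels and 8 bins.

    ``level = clip(round(255 · (HU − lo) / (hi − lo)), 0, 255)`` on surface
    pixels; values outside the window saturate at the end bins.
    """
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ConfigError(f"quantization window must have lower < upper, got {window}")
    surf = dg.surface_mask
    levels = np.full(dg.shape, -1, dtype=np.int16)
    hu = dg.values_hu[surf]
    lv = np.clip(np.rint(255.0 * (hu - lo) / (hi - lo)), 0, 255).astype(np.int16)
    levels[surf] = lv
    bins = np.zeros(dg.shape, dtype=np.int8)
    bins[surf] = level_to_bin(lv)
    return QuantizedDensitogram(levels=levels, bins=bins, window=(lo, hi), source=dg)


@dataclass
class MaximumRegion:
    """One connected density maximum (pixels in the top two bins).

    Two locations are carried per region: the area centroid and the *peak*
    (the pixel with the highest HU).  The centroid describes where the
    region sits, but its position shifts whenever the region grows or
    shrinks; the peak tracks the location of the underlying density maximum
    and is invariant under any monotone rescaling of the densitogram, so it
    is the location used for longitudinal position comparisons.
    """

    pixels: np.ndarray          # (n, 2) array of (row, col)
    area: int                   # pixel count
    centroid_px: tuple[float, float]   # (row, col), area centroid
    peak_px: tuple[float, float]       # (row, col), highest-HU pixel
    centroid_grid: tuple[float, float] | None = None  # (x, y) on the unit grid
    peak_grid: tuple[float, float] | None = None


def detect_maxima(
    q: QuantizedDensitogram,
    min_area: int = 3,
    connectivity: int = 8,
) -> list[MaximumRegion]:
    """Connected components of top-two-bin pixels, largest first.

    ``min_area`` (default 3 px) suppresses single-pixel speckles; set to 1
    for the strict literal definition.  ``connectivity`` is 4 or 8
    (default 8).  An empty list is a valid result.
    """
    if connectivity not in (4, 8):
        raise ConfigError("connectivity must be 4 or 8")
    if min_area < 1:
        raise ConfigError("min_area must be >= 1")
    top = q.bins >= TOP_BIN_THRESHOLD
    labels = measure.label(top, connectivity=1 if connectivity == 4 else 2)
    hu = q.source.values_hu
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        coords = rp.coords
        vals = hu[coords[:, 0], coords[:, 1]]
        peak = coords[int(np.argmax(vals))]
        regions.append(
            MaximumRegion(
                pixels=coords.copy(),
                area=int(rp.area),
                centroid_px=(float(rp.centroid[0]), float(rp.centroid[1])),
                peak_px=(float(peak[0]), float(peak[1])),
            )
        )
    regions.sort(key=lambda r: (-r.area, r.centroid_px))
    return regions


@dataclass
class GridFrame:
    """Affine frame mapping surface pixels onto a fixed n × n unit grid.

    The frame is the tight axis-aligned bounding box of the surface mask;
    the full box always spans ``n_units`` grid units in both directions, so
    grid coordinates are invariant to the physical size of the joint.
    """

    row_min: float
    row_max: float
    col_min: float
    col_max: float
    n_units: int = 30

    @classmethod
    def from_surface_mask(cls, surface_mask: np.ndarray, n_units: int = 30) -> "GridFrame":
        if not np.asarray(surface_mask).any():
            raise InputError("surface mask is empty; cannot build a grid frame")
        rows, cols = np.nonzero(surface_mask)
        return cls(
            row_min=float(rows.min()),
            row_max=float(rows.max()),
            col_min=float(cols.min()),
            col_max=float(cols.max()),
            n_units=n_units,
        )

    def pixel_to_grid(self, row: float, col: float, tol: float = 1e-9) -> tuple[float, float]:
        """Map a (row, col) pixel point to continuous (x, y) grid coordinates.

        x runs along columns, y along rows; the bounding-box corners map to
        (0, 0) and (n_units, n_units).  Points outside the box raise
        :class:`FrameError`.
        """
        if (row < self.row_min - tol or row > self.row_max + tol
                or col < self.col_min - tol or col > self.col_max + tol):
            raise FrameError(
                f"pixel ({row}, {col}) lies outside the grid frame "
                f"rows [{self.row_min}, {self.row_max}] cols [{self.col_min}, {self.col_max}]"
            )
        col_span = self.col_max - self.col_min
        row_span = self.row_max - self.row_min
        x = self.n_units / 2 if col_span == 0 else self.n_units * (col - self.col_min) / col_span
        y = self.n_units / 2 if row_span == 0 else self.n_units * (row - self.row_min) / row_span
        return (float(x), float(y))


def to_grid(region: MaximumRegion | tuple[float, float], frame: GridFrame) -> tuple[float, float]:
    """Grid coordinates of a region's area centroid (or of a raw pixel point)."""
    if isinstance(region, MaximumRegion):
        row, col = region.centroid_px
    else:
        row, col = region
    return frame.pixel_to_grid(row, col)


@dataclass
class MarResult:
    """Maximum area ratio: density-maximum pixels over joint-surface pixels."""

    mar: float                  # ratio in [0, 1]
    mar_pct: float              # same, ×100
    maximum_area_px: int
    surface_area_px: int
    per_region: list[dict]      # area / ratio / centroid per region


def compute_mar(maxima: list[MaximumRegion], surface_mask: np.ndarray) -> MarResult:
    """MAR over the union of all detected maxima (regions are disjoint
    connected components, so the union is the sum of areas)."""
    surface_px = int(np.asarray(surface_mask).sum())
    if surface_px == 0:
        raise InputError("joint surface is empty; MAR undefined")
    seen = set()
    union = 0
    per_region = []
    for reg in maxima:
        fresh = [tuple(p) for p in reg.pixels if tuple(p) not in seen]
        seen.update(fresh)
        union += len(fresh)
        per_region.append(
            {
                "area_px": reg.area,
                "ratio": reg.area / surface_px,
                "centroid_px": reg.centroid_px,
                "centroid_grid": reg.centroid_grid,
                "peak_px": reg.peak_px,
                "peak_grid": reg.peak_grid,
            }
        )
    mar = union / surface_px
    return MarResult(
        mar=float(mar),
        mar_pct=float(100.0 * mar),
        maximum_area_px=union,
        surface_area_px=surface_px,
        per_region=per_region,
    )
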