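"""Slow, loop-based reference implementation of the surface-anchored MIP.

This module re-derives the projection pixel by pixel with its own nearest
-voxel and trilinear interpolation code.  It shares nothing with
:func:`ctoam.projection.project_mip` beyond the ray/pixel conventions it is
meant to validate, and exists purely as a cross-check for tests and the
verification script: on small volumes the two routes must agree to within
interpolation tolerance.
"""

from __future__ import annotations

import numpy as np

from .projection import Densitogram, ViewSpec
from .volume import BoneMask, CtVolume

__all__ = ["mip_bruteforce"]


def _masked_trilinear_point(vol: np.ndarray, mask: np.ndarray,
                            x: float, y: float, z: float) -> float:
    """Trilinear interpolation over in-mask corner voxels, renormalized.

    Coordinates are clamped to the grid; corner voxels outside the mask get
    zero weight.  Returns −inf when no in-mask corner carries weight.
    """
    nx, ny, nz = vol.shape
    x = min(max(x, 0.0), nx - 1.0)
    y = min(max(y, 0.0), ny - 1.0)
    z = min(max(z, 0.0), nz - 1.0)
    i0 = min(max(int(np.floor(x)), 0), nx - 2)
    j0 = min(max(int(np.floor(y)), 0), ny - 2)
    k0 = min(max(int(np.floor(z)), 0), nz - 2)
    fx, fy, fz = x - i0, y - j0, z - k0
    num = 0.0
    den = 0.0
    for di, wi in ((i0, 1 - fx), (i0 + 1, fx)):
        for dj, wj in ((j0, 1 - fy), (j0 + 1, fy)):
            for dk, wk in ((k0, 1 - fz), (k0 + 1, fz)):
                if mask[di, dj, dk]:
                    w = wi * wj * wk
                    num += w * vol[di, dj, dk]
                    den += w
    return num / den if den > 0 else -np.inf


def _nearest_in_mask(mask: np.ndarray, x: float, y: float, z: float) -> bool:
    i = int(np.floor(x + 0.5))
    j = int(np.floor(y + 0.5))
    k = int(np.floor(z + 0.5))
    if i < 0 or j < 0 or k < 0:
        return False
    if i >= mask.shape[0] or j >= mask.shape[1] or k >= mask.shape[2]:
        return False
    return bool(mask[i, j, k])


def mip_bruteforce(
    volume: CtVolume,
    mask: BoneMask,
    view: ViewSpec,
    step: float | None = None,
) -> Densitogram:
    """Per-pixel ray enumeration equivalent of ``project_mip``."""
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    if step is None:
        step = float(spacing.min()) / 2.0

    d = view.projection_axis
    e0, e1 = view.in_plane_basis
    pixel = view.pixel_size
    if pixel is None:
        pixel = float(min(np.abs(e0) @ spacing, np.abs(e1) @ spacing))

    # same padded mask-bounding-box convention as the fast path
    idx_lo, idx_hi = [], []
    for ax in range(3):
        hits = [i for i in range(mask.data.shape[ax])
                if np.take(mask.data, i, axis=ax).any()]
        idx_lo.append(hits[0])
        idx_hi.append(hits[-1])
    lo = origin + (np.asarray(idx_lo) - 1) * spacing
    hi = origin + (np.asarray(idx_hi) + 1) * spacing
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    umin, umax = (corners @ e0).min(), (corners @ e0).max()
    vmin, vmax = (corners @ e1).min(), (corners @ e1).max()
    tmin, tmax = (corners @ d).min(), (corners @ d).max()

    nu = max(int(np.ceil((umax - umin) / pixel)), 1)
    nv = max(int(np.ceil((vmax - vmin) / pixel)), 1)
    nt = int(np.floor((tmax - tmin) / step)) + 1
    nd = int(np.floor(view.mip_depth / step)) + 1

    values = np.full((nv, nu), np.nan)
    surf = np.zeros((nv, nu), dtype=bool)
    m = mask.data
    vox = volume.voxels
    for r in range(nv):
        v = vmin + (r + 0.5) * pixel
        for c in range(nu):
            u = umin + (c + 0.5) * pixel
            t_entry = None
            for it in range(nt):
                t = tmin + it * step
                p = u * e0 + v * e1 + t * d
                ix = (p - origin) / spacing
                if _nearest_in_mask(m, *ix):
                    t_entry = t
                    break
            if t_entry is None:
                continue
            best = -np.inf
            for k in range(nd):
                t = t_entry + k * step
                p = u * e0 + v * e1 + t * d
                ix = (p - origin) / spacing
                best = max(best, _masked_trilinear_point(vox, m, *ix))
            surf[r, c] = True
            values[r, c] = best

    return Densitogram(
        values_hu=values,
        surface_mask=surf,
        pixel_size=pixel,
        view_name=view.name,
        mip_depth=view.mip_depth,
        u0=float(umin + 0.5 * pixel),
        v0=float(vmin + 0.5 * pixel),
        subject_id=volume.subject_id,
        timepoint=volume.timepoint,
    )
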