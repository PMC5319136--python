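"""View geometry and the surface-anchored maximum intensity projection.

The articular surface is imaged by orthographic (parallel-ray) projection:
for every pixel of the 2D image plane a ray is cast along the viewing
direction; where it first enters the bone mask — the articular surface — a
segment of length ``mip_depth`` (default 1.5 mm) extends *into* the bone,
and the pixel value is the maximum HU sampled along that segment.
Restricting the maximum to a shallow sub-surface band is what makes the
projection a map of the subchondral bone plate rather than of the whole
bone.

Sampling: rays are marched at a step of ``min(spacing)/2``; the mask is
sampled with nearest-neighbour lookup (a sample belongs to the bone iff its
nearest voxel is foreground) and HU with *masked* trilinear interpolation:
the eight surrounding voxels are blended with trilinear weights, voxels
outside the bone mask get zero weight, and the weights are renormalized.
Voxels outside the mask therefore never contribute to any pixel value —
near-surface samples are not diluted by soft-tissue HU.

View frames
-----------
``proximal``: sight direction (0, 0, −1) — looking down the z (slice) axis;
image columns run along x (medial–lateral), rows along y.
``dorsal``: the proximal frame tilted backwards by 90° about the
medial–lateral axis, giving sight direction (0, 1, 0); rows then run along z.
Densitogram arrays are row-major with ``row = in_plane_basis[1]`` and
``column = in_plane_basis[0]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .errors import ConfigError, GeometryError, ProjectionError
from .volume import BoneMask, CtVolume

__all__ = [
    "ViewSpec",
    "Densitogram",
    "make_view",
    "proximal_view",
    "dorsal_view",
    "default_views",
    "project_mip",
]

DEFAULT_MIP_DEPTH_MM = 1.5


@dataclass
class ViewSpec:
    """An orthographic view: sight direction plus an in-plane orthonormal basis."""

    name: str
    projection_axis: np.ndarray        # unit vector, direction of sight
    in_plane_basis: tuple[np.ndarray, np.ndarray]  # (column axis, row axis)
    pixel_size: float | None = None    # mm; None → smallest in-plane voxel spacing
    mip_depth: float = DEFAULT_MIP_DEPTH_MM

    def __post_init__(self) -> None:
        d = np.asarray(self.projection_axis, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.all(np.isfinite(d)):
            raise GeometryError("projection axis is degenerate")
        self.projection_axis = d / n
        e0 = np.asarray(self.in_plane_basis[0], dtype=float)
        e1 = np.asarray(self.in_plane_basis[1], dtype=float)
        for v in (e0, e1):
            if np.linalg.norm(v) == 0:
                raise GeometryError("in-plane basis vector is degenerate")
        e0 = e0 / np.linalg.norm(e0)
        # Gram-Schmidt: basis must be orthonormal and orthogonal to the axis
        e1 = e1 - (e1 @ e0) * e0
        if np.linalg.norm(e1) < 1e-9:
            raise GeometryError("in-plane basis vectors are parallel")
        e1 = e1 / np.linalg.norm(e1)
        if abs(e0 @ self.projection_axis) > 1e-9 or abs(e1 @ self.projection_axis) > 1e-9:
            raise GeometryError("in-plane basis is not orthogonal to the projection axis")
        self.in_plane_basis = (e0, e1)
        if self.mip_depth <= 0:
            raise ConfigError("mip_depth must be positive")


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle_deg``."""
    a = np.deg2rad(angle_deg)
    k = axis / np.linalg.norm(axis)
    return (
        v * np.cos(a)
        + np.cross(k, v) * np.sin(a)
        + k * (k @ v) * (1 - np.cos(a))
    )


def make_view(
    name: str,
    tilt_deg: float = 0.0,
    base_axis=(0.0, 0.0, -1.0),
    tilt_axis=(1.0, 0.0, 0.0),
    base_basis=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    pixel_size: float | None = None,
    mip_depth: float = DEFAULT_MIP_DEPTH_MM,
) -> ViewSpec:
    """Construct a view by tilting the base (proximal) frame about the
    medial–lateral axis.

    ``tilt_deg = 0`` reproduces the base view; ``tilt_deg = 90`` with the
    default axes turns the downward proximal sight (0,0,−1) into the dorsal
    sight (0,1,0).
    """
    base_axis = np.asarray(base_axis, dtype=float)
    tilt_axis = np.asarray(tilt_axis, dtype=float)
    if np.linalg.norm(base_axis) == 0 or np.linalg.norm(tilt_axis) == 0:
        raise GeometryError("view axes must be non-zero")
    axis = _rotate(base_axis, tilt_axis, tilt_deg)
    e0 = _rotate(np.asarray(base_basis[0], dtype=float), tilt_axis, tilt_deg)
    e1 = _rotate(np.asarray(base_basis[1], dtype=float), tilt_axis, tilt_deg)
    return ViewSpec(name, axis, (e0, e1), pixel_size=pixel_size, mip_depth=mip_depth)


def proximal_view(mip_depth: float = DEFAULT_MIP_DEPTH_MM,
                  pixel_size: float | None = None) -> ViewSpec:
    return make_view("proximal", 0.0, mip_depth=mip_depth, pixel_size=pixel_size)


def dorsal_view(mip_depth: float = DEFAULT_MIP_DEPTH_MM,
                pixel_size: float | None = None) -> ViewSpec:
    """Proximal frame tilted backwards ~90° about the medial–lateral axis."""
    return make_view("dorsal", 90.0, mip_depth=mip_depth, pixel_size=pixel_size)


def default_views(mip_depth: float = DEFAULT_MIP_DEPTH_MM) -> list[ViewSpec]:
    return [proximal_view(mip_depth), dorsal_view(mip_depth)]


@dataclass
class Densitogram:
    """2D map of maximum subchondral HU (and, once calibrated, density).

    ``values_hu`` is defined (finite) exactly where ``surface_mask`` is true;
    elsewhere it is NaN.  ``values_density`` stays ``None`` until the
    calibration stage fills it.  ``u0``/``v0`` are the image-plane
    coordinates (mm) of pixel (row 0, col 0)'s centre, kept so that world
    points can be mapped into pixel coordinates.
    """

    values_hu: np.ndarray
    surface_mask: np.ndarray
    pixel_size: float
    view_name: str
    mip_depth: float
    u0: float
    v0: float
    values_density: np.ndarray | None = None
    subject_id: str | None = None
    timepoint: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_hu.shape  # type: ignore[return-value]

    def plane_to_pixel(self, u: float, v: float) -> tuple[float, float]:
        """Continuous (row, col) pixel coordinates of an image-plane point (mm)."""
        return ((v - self.v0) / self.pixel_size, (u - self.u0) / self.pixel_size)

    def surface_values(self, calibrated: bool = False) -> np.ndarray:
        vals = self.values_density if calibrated else self.values_hu
        if vals is None:
            raise ProjectionError("densitogram has not been calibrated")
        return vals[self.surface_mask]


def _nearest_lookup(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Nearest-voxel lookup; points outside the grid return False/0.

    ``idx`` has shape (..., 3) in voxel-index units.  Nearest voxel is
    ``floor(idx + 0.5)`` per axis (round half up, matching the ray oracle).
    """
    near = np.floor(idx + 0.5).astype(np.int64)
    inb = np.ones(idx.shape[:-1], dtype=bool)
    for ax in range(3):
        inb &= (near[..., ax] >= 0) & (near[..., ax] <= arr.shape[ax] - 1)
    out = np.zeros(idx.shape[:-1], dtype=arr.dtype)
    if inb.any():
        sel = near[inb]
        out[inb] = arr[sel[:, 0], sel[:, 1], sel[:, 2]]
    return out


def _masked_trilinear(vol: np.ndarray, mask: np.ndarray, idx: np.ndarray):
    """Trilinear interpolation restricted to in-mask voxels.

    Coordinates are clamped to the grid; each of the eight corner voxels
    contributes its trilinear weight only if it is inside the mask, and the
    result is renormalized by the in-mask weight sum.  Returns
    ``(values, weight_sum)``; where ``weight_sum`` is 0 the sample touches
    no bone voxel and has no defined value.
    """
    shp = np.asarray(vol.shape)
    idx = np.clip(idx, 0.0, (shp - 1).astype(float))
    i0 = np.floor(idx).astype(np.int64)
    i0 = np.minimum(i0, shp - 2)  # ensure i0+1 is a valid corner
    i0 = np.maximum(i0, 0)
    frac = idx - i0
    num = np.zeros(idx.shape[:-1])
    den = np.zeros(idx.shape[:-1])
    for dx in (0, 1):
        wx = frac[..., 0] if dx else 1.0 - frac[..., 0]
        for dy in (0, 1):
            wy = frac[..., 1] if dy else 1.0 - frac[..., 1]
            for dz in (0, 1):
                wz = frac[..., 2] if dz else 1.0 - frac[..., 2]
                ii = i0[..., 0] + dx
                jj = i0[..., 1] + dy
                kk = i0[..., 2] + dz
                w = wx * wy * wz * mask[ii, jj, kk]
                num += w * vol[ii, jj, kk]
                den += w
    vals = np.full(idx.shape[:-1], -np.inf)
    ok = den > 0
    vals[ok] = num[ok] / den[ok]
    return vals, den


def project_mip(
    volume: CtVolume,
    mask: BoneMask,
    view: ViewSpec,
    step: float | None = None,
) -> Densitogram:
    """Surface-anchored maximum intensity projection of a masked volume.

    Parameters
    ----------
    volume, mask:
        Congruent HU volume and binary bone mask.
    view:
        View frame; ``view.mip_depth`` sets the sub-surface depth (mm).
    step:
        Ray sampling step in mm; default ``min(spacing)/2``.

    Returns
    -------
    Densitogram
        Pixels whose ray never enters the mask have ``surface_mask`` false
        and NaN value.
    """
    mask.check_congruent(volume)
    if not mask.data.any():
        raise ProjectionError("bone mask is empty")
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    if step is None:
        step = float(spacing.min()) / 2.0
    if step <= 0:
        raise ConfigError("sampling step must be positive")
    if view.mip_depth < step:
        raise ConfigError(
            f"mip_depth {view.mip_depth} mm is smaller than the sampling step {step} mm"
        )

    d = view.projection_axis
    e0, e1 = view.in_plane_basis
    pixel = view.pixel_size
    if pixel is None:
        pixel = float(min(np.abs(e0) @ spacing, np.abs(e1) @ spacing))

    # Image-plane / depth extent from the bone's bounding box, padded by one
    # voxel per axis: rays outside it can never enter the mask, so the
    # densitogram is identical to one computed over the whole volume.
    idx_lo, idx_hi = [], []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        prof = mask.data.any(axis=other)
        nz = np.nonzero(prof)[0]
        idx_lo.append(int(nz[0]))
        idx_hi.append(int(nz[-1]))
    lo = origin + (np.asarray(idx_lo) - 1) * spacing
    hi = origin + (np.asarray(idx_hi) + 1) * spacing
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    u_all, v_all, t_all = corners @ e0, corners @ e1, corners @ d
    umin, umax = float(u_all.min()), float(u_all.max())
    vmin, vmax = float(v_all.min()), float(v_all.max())
    tmin, tmax = float(t_all.min()), float(t_all.max())

    nu = max(int(np.ceil((umax - umin) / pixel)), 1)
    nv = max(int(np.ceil((vmax - vmin) / pixel)), 1)
    uu = umin + (np.arange(nu) + 0.5) * pixel
    vv = vmin + (np.arange(nv) + 0.5) * pixel
    nt = int(np.floor((tmax - tmin) / step)) + 1
    tt = tmin + np.arange(nt) * step

    # Stage 1: march every ray through the volume, find the first mask entry.
    pts = (
        uu[None, :, None, None] * e0[None, None, None, :]
        + vv[:, None, None, None] * e1[None, None, None, :]
        + tt[None, None, :, None] * d[None, None, None, :]
    )  # (nv, nu, nt, 3)
    idx = (pts - origin) / spacing
    in_bone = _nearest_lookup(mask.data, idx)
    hit = in_bone.any(axis=2)
    first = in_bone.argmax(axis=2)

    values = np.full((nv, nu), np.nan)
    if hit.any():
        rows, cols = np.nonzero(hit)
        t_entry = tt[first[rows, cols]]
        # Stage 2: sample the depth segment anchored at the surface entry.
        nd = int(np.floor(view.mip_depth / step)) + 1
        td = t_entry[:, None] + np.arange(nd)[None, :] * step  # (nhit, nd)
        p2 = (
            uu[cols][:, None, None] * e0
            + vv[rows][:, None, None] * e1
            + td[:, :, None] * d
        )  # (nhit, nd, 3)
        idx2 = (p2 - origin) / spacing
        hu, _ = _masked_trilinear(volume.voxels, mask.data, idx2)
        values[rows, cols] = hu.max(axis=1)

    return Densitogram(
        values_hu=values,
        surface_mask=hit,
        pixel_size=pixel,
        view_name=view.name,
        mip_depth=view.mip_depth,
        u0=float(uu[0]),
        v0=float(vv[0]),
        subject_id=volume.subject_id,
        timepoint=volume.timepoint,
        meta={"step": step, "nu": nu, "nv": nv},
    )
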