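"""Seedable synthetic CT volumes emulating a trochlea-like tarsal bone.

The generator builds everything downstream stages need, with known ground
truth:

* **Bone**: two overlapping partial (upper-half) cylinders with parallel
  medial–lateral axes stand in for the medial and lateral trochlear ridges.
  Each ridge has a high-density subchondral *shell* of configurable
  thickness over a lower-density trabecular interior — the minimal geometry
  that shows a curved articular surface in both the proximal and the dorsal
  view.
* **Hotspots**: isotropic Gaussian density bumps anchored on the shell
  surface provide smooth, parameterized density maxima whose locations the
  pipeline should recover.
* **Phantom**: cylindrical inserts of known hydroxyapatite-equivalent
  density placed below the bone, each with an eroded cylindrical ROI, so
  the calibration stage can be exercised and checked against the true
  HU→density map.
* **Noise**: additive Gaussian noise in HU applied after the density→HU
  mapping (the simplest CT-plausible model; default SD 10 HU).

Bone and insert voxels carry density mapped through the *inverse* of the
configured true calibration (``HU = (density − intercept) / slope``), so
applying the true calibration to a noise-free volume returns the configured
densities exactly.

Cohorts: :func:`generate_cohort` produces paired (t1, t2) scans per
subject.  At t2 every bone density is the t1 density times a growth factor
(applied before noise); hotspot anchors never move.  Each subject gets a
recorded multiplicative jitter on its base densities, and every scan is
seeded with a structured key derived from the cohort root seed, so cohorts
are reproducible and all scans statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import PhantomSpec
from .errors import CohortError, GeometryError, SpecError
from .projection import ViewSpec, default_views
from .volume import BoneMask, CtVolume

__all__ = [
    "Ridge",
    "Hotspot",
    "Insert",
    "SyntheticSpec",
    "GroundTruth",
    "SubjectScan",
    "PairedSubject",
    "Cohort",
    "default_spec",
    "compact_spec",
    "spec_to_dict",
    "spec_from_dict",
    "generate_volume",
    "generate_cohort",
    "phantom_spec_for",
]



@dataclass
class Ridge:
    """A partial cylinder: axis through ``center`` along ``axis``, keeping the
    half on the ``up`` side (the articular, convex half)."""

    center: tuple[float, float, float]   # mm
    radius: float                        # mm
    length: float                        # mm along the axis
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class Hotspot:
    """Gaussian density bump anchored on the bone surface."""

    anchor: tuple[float, float, float]   # mm, on the shell surface
    amplitude: float                     # mg HA/cm³ added at the anchor
    sigma: float                         # mm


@dataclass
class Insert:
    """Cylindrical phantom insert; the ROI is a coaxial eroded cylinder."""

    density: float                       # mg HA/cm³
    center: tuple[float, float, float]   # mm
    radius: float                        # mm
    length: float                        # mm along x
    roi_radius: float                    # mm, < radius (avoids edge voxels)
    roi_length: float                    # mm, < length


@dataclass
class SyntheticSpec:
    """Full description of one synthetic scan; identical spec + seed give a
    bit-identical volume."""

    volume_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    ridges: tuple[Ridge, ...]
    shell_thickness: float               # mm
    shell_base_density: float            # mg HA/cm³
    interior_density: float              # mg HA/cm³
    background_hu: float
    hotspots: tuple[Hotspot, ...]
    inserts: tuple[Insert, ...]
    true_calibration: tuple[float, float]  # (slope mg/cm³ per HU, intercept mg/cm³)
    noise_sd: float                      # HU
    rng_seed: int | tuple[int, ...] = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise SpecError("voxel spacing must be positive in all axes")
        if any(n < 2 for n in self.volume_shape):
            raise SpecError("volume shape must be at least 2 voxels per axis")
        if self.shell_thickness < min(self.voxel_spacing):
            raise SpecError("shell thickness must be at least one voxel")
        if any(h.sigma <= 0 for h in self.hotspots):
            raise SpecError("hotspot sigma must be positive")
        dens = [i.density for i in self.inserts]
        if any(d < 0 for d in dens):
            raise SpecError("insert densities must be non-negative")
        if len(set(dens)) != len(dens):
            raise SpecError("insert densities must be distinct")
        slope, _ = self.true_calibration
        if slope == 0 or not np.isfinite(slope):
            raise SpecError("true calibration slope must be finite and non-zero")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be non-negative")
        extent = np.asarray(self.volume_shape) * np.asarray(self.voxel_spacing)
        for r in self.ridges:
            c = np.asarray(r.center, dtype=float)
            ax = np.asarray(r.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            # per-axis half-extent of the tube: length along the axis,
            # radius in the perpendicular plane
            half = np.abs(ax) * r.length / 2 + r.radius * np.sqrt(
                np.clip(1.0 - ax**2, 0.0, 1.0)
            )
            if np.any(c - half < -1e-9) or np.any(c + half > extent + 1e-9):
                raise GeometryError(
                    f"ridge at {r.center} (radius {r.radius}) exceeds the volume "
                    f"extent {tuple(extent)}"
                )

    def scaled(self, factor: float) -> "SyntheticSpec":
        """Spec with all *bone* densities multiplied by ``factor``.

        Phantom inserts and background are deliberately untouched: growth
        changes the bone, not the reference standard.
        """
        return replace(
            self,
            shell_base_density=self.shell_base_density * factor,
            interior_density=self.interior_density * factor,
            hotspots=tuple(
                replace(h, amplitude=h.amplitude * factor) for h in self.hotspots
            ),
        )


@dataclass
class HotspotViewLocation:
    """Ground-truth position of one hotspot in one view."""

    hotspot_index: int
    u_mm: float                 # image-plane coordinates (column direction)
    v_mm: float                 # image-plane coordinates (row direction)
    grid_x: float               # analytic 30×30-grid estimate
    grid_y: float
    incidence: float            # cos(angle between surface normal and −sight)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline should recover."""

    hotspot_anchors_mm: np.ndarray                  # (n_hotspots, 3)
    view_locations: dict[str, list[HotspotViewLocation]]
    true_calibration: tuple[float, float]
    bone_mask: BoneMask = field(repr=False)
    scale_t1: float = 1.0
    scale_t2: float = 1.0


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Study-scale synthetic talus.

    40 × 32 × 55 mm volume at 0.5 × 0.5 × 1.25 mm voxels (1.25 mm matching
    the collimation of the emulated scans); two ridges of radius 9 and 8 mm;
    2.5 mm shell at 550 mg HA/cm³ over a 250 mg HA/cm³ interior; one
    hotspot per ridge (350 mg HA/cm³, σ = 2 mm) — the medial one placed
    proximally (40° from vertical), the lateral one more distally/dorsally
    (70°); five phantom inserts at 0/100/200/400/800 mg HA/cm³; true
    calibration 0.8 mg HA/cm³ per HU with intercept −3; noise SD 10 HU.
    """
    med_c = np.array([13.0, 16.0, 30.0])
    lat_c = np.array([26.0, 16.0, 30.0])
    r_med, r_lat = 9.0, 8.0
    a_med, a_lat = np.deg2rad(40.0), np.deg2rad(70.0)  # angle from +z toward −y

    def on_surface(center, radius, angle):
        return (
            float(center[0]),
            float(center[1] - radius * np.sin(angle)),
            float(center[2] + radius * np.cos(angle)),
        )

    inserts = tuple(
        Insert(density=d, center=(20.0, y, 8.0), radius=2.2, length=24.0,
               roi_radius=1.7, roi_length=20.0)
        for d, y in zip((0.0, 100.0, 200.0, 400.0, 800.0), (6.0, 11.0, 16.0, 21.0, 26.0))
    )
    return SyntheticSpec(
        volume_shape=(80, 64, 44),
        voxel_spacing=(0.5, 0.5, 1.25),
        ridges=(
            Ridge(center=tuple(med_c), radius=r_med, length=14.0),
            Ridge(center=tuple(lat_c), radius=r_lat, length=14.0),
        ),
        shell_thickness=2.5,
        shell_base_density=550.0,
        interior_density=250.0,
        background_hu=0.0,
        hotspots=(
            Hotspot(anchor=on_surface(med_c, r_med, a_med), amplitude=350.0, sigma=2.0),
            Hotspot(anchor=on_surface(lat_c, r_lat, a_lat), amplitude=350.0, sigma=2.0),
        ),
        inserts=inserts,
        true_calibration=(0.8, -3.0),
        noise_sd=10.0,
        rng_seed=seed,
    )


def compact_spec(seed: int = 0) -> SyntheticSpec:
    """Small-volume variant (36 × 28 × 25 mm at 1 × 1 × 1.25 mm voxels) used
    for simulation studies that need thousands of volumes.  Same anatomy and
    densities as :func:`default_spec`, coarser sampling, three inserts."""
    med_c = np.array([12.0, 14.0, 12.5])
    lat_c = np.array([23.0, 14.0, 12.5])
    r_med, r_lat = 7.0, 6.5
    a_med, a_lat = np.deg2rad(40.0), np.deg2rad(70.0)
    inserts = tuple(
        Insert(density=d, center=(17.0, y, 4.0), radius=2.0, length=16.0,
               roi_radius=1.4, roi_length=12.0)
        for d, y in zip((100.0, 400.0, 800.0), (7.0, 14.0, 21.0))
    )
    return SyntheticSpec(
        volume_shape=(36, 28, 20),
        voxel_spacing=(1.0, 1.0, 1.25),
        ridges=(
            Ridge(center=tuple(med_c), radius=r_med, length=12.0),
            Ridge(center=tuple(lat_c), radius=r_lat, length=12.0),
        ),
        shell_thickness=2.5,
        shell_base_density=550.0,
        interior_density=250.0,
        background_hu=0.0,
        hotspots=(
            Hotspot(
                anchor=(12.0, float(14.0 - r_med * np.sin(a_med)),
                        float(12.5 + r_med * np.cos(a_med))),
                amplitude=350.0, sigma=2.0),
            Hotspot(
                anchor=(23.0, float(14.0 - r_lat * np.sin(a_lat)),
                        float(12.5 + r_lat * np.cos(a_lat))),
                amplitude=350.0, sigma=2.0),
        ),
        inserts=inserts,
        true_calibration=(0.8, -3.0),
        noise_sd=10.0,
        rng_seed=seed,
    )


def _plain(obj):
    """Recursively convert numpy scalars/tuples to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Plain-dict form of a spec (YAML/JSON serializable)."""
    from dataclasses import asdict

    return _plain(asdict(spec))


def spec_from_dict(d: dict) -> SyntheticSpec:
    """Inverse of :func:`spec_to_dict`."""
    d = dict(d)
    d["ridges"] = tuple(Ridge(**{**r, "center": tuple(r["center"]),
                                 "axis": tuple(r.get("axis", (1.0, 0.0, 0.0))),
                                 "up": tuple(r.get("up", (0.0, 0.0, 1.0)))})
                        for r in d["ridges"])
    d["hotspots"] = tuple(Hotspot(**{**h, "anchor": tuple(h["anchor"])})
                          for h in d["hotspots"])
    d["inserts"] = tuple(Insert(**{**i, "center": tuple(i["center"])})
                         for i in d["inserts"])
    d["volume_shape"] = tuple(d["volume_shape"])
    d["voxel_spacing"] = tuple(d["voxel_spacing"])
    d["true_calibration"] = tuple(d["true_calibration"])
    if isinstance(d.get("rng_seed"), list):
        d["rng_seed"] = tuple(d["rng_seed"])
    return SyntheticSpec(**d)


def _voxel_centers(spec: SyntheticSpec) -> np.ndarray:
    """(nx, ny, nz, 3) world coordinates (mm) of voxel centres."""
    axes = [np.arange(n) * s for n, s in zip(spec.volume_shape, spec.voxel_spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _ridge_fields(points: np.ndarray, ridge: Ridge):
    """Return (inside, radial_distance, axial_coord, up_component)."""
    c = np.asarray(ridge.center)
    ax = np.asarray(ridge.axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    up = np.asarray(ridge.up, dtype=float)
    up = up - (up @ ax) * ax
    if np.linalg.norm(up) == 0:
        raise GeometryError("ridge 'up' direction is parallel to its axis")
    up = up / np.linalg.norm(up)
    rel = points - c
    s = rel @ ax
    radial = rel - s[..., None] * ax[None, None, None, :]
    rad = np.linalg.norm(radial, axis=-1)
    upc = radial @ up
    inside = (np.abs(s) <= ridge.length / 2) & (rad <= ridge.radius) & (upc >= 0)
    return inside, rad, s, upc


def _cylinder_mask(points: np.ndarray, center, radius, length, axis=(1.0, 0.0, 0.0)):
    c = np.asarray(center)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    rel = points - c
    s = rel @ ax
    rad = np.linalg.norm(rel - s[..., None] * ax, axis=-1)
    return (np.abs(s) <= length / 2) & (rad <= radius)


def phantom_spec_for(spec: SyntheticSpec) -> PhantomSpec:
    """Phantom ROI masks (eroded insert cylinders) aligned with the volume."""
    pts = _voxel_centers(spec)
    inserts = [
        (ins.density, _cylinder_mask(pts, ins.center, ins.roi_radius, ins.roi_length))
        for ins in spec.inserts
    ]
    return PhantomSpec(inserts=inserts)


def _build_bone(spec: SyntheticSpec, pts: np.ndarray):
    """Bone mask, shell mask and density field (mg HA/cm³, 0 outside bone)."""
    mask = np.zeros(spec.volume_shape, dtype=bool)
    interior = np.zeros(spec.volume_shape, dtype=bool)
    t = spec.shell_thickness
    for ridge in spec.ridges:
        inside, rad, s, upc = _ridge_fields(pts, ridge)
        mask |= inside
        # a voxel is interior only if it is at least one shell thickness away
        # from every boundary of the partial cylinder it belongs to (the flat
        # base is treated as interior: it is not an articular surface)
        interior |= inside & (rad <= ridge.radius - t) & (np.abs(s) <= ridge.length / 2 - t)
    shell = mask & ~interior
    density = np.zeros(spec.volume_shape)
    density[mask] = spec.interior_density
    density[shell] = spec.shell_base_density
    for h in spec.hotspots:
        d2 = np.sum((pts - np.asarray(h.anchor)) ** 2, axis=-1)
        bump = h.amplitude * np.exp(-d2 / (2.0 * h.sigma**2))
        density[mask] += bump[mask]
    return mask, shell, density


def _ground_truth(spec: SyntheticSpec, mask: BoneMask,
                  views: Sequence[ViewSpec] | None = None,
                  min_incidence: float = 0.25) -> GroundTruth:
    """Project hotspot anchors into the default view frames.

    The analytic grid estimate maps the anchor's image-plane position into
    the analytic bounding box of the articular surface; a hotspot is listed
    for a view when its outward surface normal faces the viewer with
    incidence cosine ≥ ``min_incidence``.
    """
    if views is None:
        views = default_views()
    anchors = np.asarray([h.anchor for h in spec.hotspots], dtype=float)
    # outward normal = radial direction on the ridge whose surface the anchor lies on
    normals = []
    for a in anchors:
        best, best_err = None, np.inf
        for ridge in spec.ridges:
            c = np.asarray(ridge.center)
            ax = np.asarray(ridge.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            rel = a - c
            radial = rel - (rel @ ax) * ax
            err = abs(np.linalg.norm(radial) - ridge.radius)
            if err < best_err and np.linalg.norm(radial) > 0:
                best_err = err
                best = radial / np.linalg.norm(radial)
        normals.append(best if best is not None else np.array([0.0, 0.0, 1.0]))

    view_locations: dict[str, list[HotspotViewLocation]] = {}
    for view in views:
        e0, e1 = view.in_plane_basis
        d = view.projection_axis
        bbox = _analytic_surface_bbox(spec, view)
        locs = []
        for i, (a, n) in enumerate(zip(anchors, normals)):
            inc = float(n @ (-d))
            if inc < min_incidence:
                continue
            u, v = float(a @ e0), float(a @ e1)
            (u0, u1), (v0, v1) = bbox
            gx = 30.0 * (u - u0) / (u1 - u0) if u1 > u0 else 15.0
            gy = 30.0 * (v - v0) / (v1 - v0) if v1 > v0 else 15.0
            locs.append(HotspotViewLocation(i, u, v, gx, gy, inc))
        view_locations[view.name] = locs
    return GroundTruth(
        hotspot_anchors_mm=anchors,
        view_locations=view_locations,
        true_calibration=spec.true_calibration,
        bone_mask=mask,
    )


def _analytic_surface_bbox(spec: SyntheticSpec, view: ViewSpec):
    """Image-plane bounding box of the articular surface, from ridge geometry.

    Computed by projecting a dense analytic sampling of each ridge's convex
    surface into the view frame (robust for any tilt, no voxels involved).
    """
    e0, e1 = view.in_plane_basis
    us, vs = [], []
    for ridge in spec.ridges:
        c = np.asarray(ridge.center)
        ax = np.asarray(ridge.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        up = np.asarray(ridge.up, dtype=float)
        up = up - (up @ ax) * ax
        up = up / np.linalg.norm(up)
        side = np.cross(ax, up)
        theta = np.linspace(-np.pi / 2, np.pi / 2, 181)
        s = np.linspace(-ridge.length / 2, ridge.length / 2, 41)
        ring = (np.cos(theta)[:, None] * up + np.sin(theta)[:, None] * side) * ridge.radius
        pts = c + s[None, :, None] * ax + ring[:, None, :]
        # include the flat base rim as well (it bounds the silhouette from above)
        us.append(pts.reshape(-1, 3) @ e0)
        vs.append(pts.reshape(-1, 3) @ e1)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    return (float(u.min()), float(u.max())), (float(v.min()), float(v.max()))


def generate_volume(
    spec: SyntheticSpec, with_ground_truth: bool = True
) -> tuple[CtVolume, BoneMask, GroundTruth | None]:
    """Render one synthetic scan.

    Bone and insert voxels are assigned density, mapped to HU through the
    inverse of the true calibration, then Gaussian HU noise (``noise_sd``)
    is added to the whole volume.  Returns the HU volume, the bone mask and
    the filled ground truth (``None`` when ``with_ground_truth`` is off,
    for bulk simulation studies that do not consume it).
    """
    spec.validate()
    slope, intercept = spec.true_calibration
    pts = _voxel_centers(spec)
    mask_arr, _, density = _build_bone(spec, pts)

    hu = np.full(spec.volume_shape, float(spec.background_hu))
    hu[mask_arr] = (density[mask_arr] - intercept) / slope
    for ins in spec.inserts:
        cyl = _cylinder_mask(pts, ins.center, ins.radius, ins.length)
        if (cyl & mask_arr).any():
            raise GeometryError("phantom insert overlaps the bone")
        hu[cyl] = (ins.density - intercept) / slope

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.volume_shape)

    volume = CtVolume(hu, spec.voxel_spacing)
    mask = BoneMask(mask_arr)
    gt = _ground_truth(spec, mask) if with_ground_truth else None
    return volume, mask, gt


# ---------------------------------------------------------------------------
# Paired cohorts


@dataclass
class SubjectScan:
    volume: CtVolume
    mask: BoneMask
    ground_truth: GroundTruth | None


@dataclass
class PairedSubject:
    subject_id: str
    t1: SubjectScan
    t2: SubjectScan
    scale: float                 # subject-level density jitter factor
    seeds: tuple                 # child seed keys used at (t1, t2)


@dataclass
class Cohort:
    subjects: list[PairedSubject]
    spec: SyntheticSpec
    growth_factor: float
    seed: int

    def scans(self):
        for subj in self.subjects:
            yield subj.subject_id, "t1", subj.t1
            yield subj.subject_id, "t2", subj.t2


def generate_cohort(
    n_subjects: int,
    growth_factor: float,
    spec: SyntheticSpec,
    seed: int,
    jitter_sd: float = 0.04,
    with_ground_truth: bool = True,
) -> Cohort:
    """Paired two-time-point cohort.

    Per subject ``i`` the bone densities are scaled by a recorded jitter
    factor ``s_i ~ N(1, jitter_sd²)`` (truncated at 0.5) at both time
    points, and additionally by ``growth_factor`` at t2 — *before* noise, so
    with zero noise and growth 1.0 the two scans are identical.  Each scan
    is seeded with the structured key ``(root seed, subject index,
    timepoint index)``, which is reproducible and collision-free across
    subjects, time points and root seeds.
    """
    if n_subjects < 2:
        raise CohortError("paired statistics need at least 2 subjects")
    if growth_factor <= 0:
        raise SpecError("growth factor must be positive")
    spec.validate()
    rng = np.random.default_rng(seed)
    scales = np.maximum(rng.normal(1.0, jitter_sd, size=n_subjects), 0.5)
    subjects = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        s1 = (int(seed), i, 0)
        s2 = (int(seed), i, 1)
        spec_t1 = replace(spec.scaled(float(scales[i])), rng_seed=s1)
        spec_t2 = replace(
            spec.scaled(float(scales[i]) * growth_factor), rng_seed=s2
        )
        scans = []
        for tp, sp in (("t1", spec_t1), ("t2", spec_t2)):
            vol, msk, gt = generate_volume(sp, with_ground_truth=with_ground_truth)
            vol.subject_id = sid
            vol.timepoint = tp
            scans.append(SubjectScan(vol, msk, gt))
        for sc in scans:
            if sc.ground_truth is not None:
                sc.ground_truth.scale_t1 = float(scales[i])
                sc.ground_truth.scale_t2 = float(scales[i]) * growth_factor
        subjects.append(PairedSubject(sid, scans[0], scans[1], float(scales[i]), (s1, s2)))
    return Cohort(subjects=subjects, spec=spec, growth_factor=growth_factor, seed=seed)
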