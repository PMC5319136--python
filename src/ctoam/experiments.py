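"""Simulation studies over the synthetic cohorts.

Each function here is a self-contained *in silico* experiment used by the
analysis drivers, the test suite and the verification script: parameter
recovery for the calibration, cross-checking the projection against the
brute-force reference, hotspot localization, the longitudinal growth
contrast, and the type-I error of the paired test under a null cohort.
All randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .calibration import apply_calibration, fit_calibration
from .cohort import compare_paired
from .pipeline import analyze_scan
from .projection import default_views, make_view, project_mip
from .reference import mip_bruteforce
from .synthetic import (
    SyntheticSpec,
    compact_spec,
    default_spec,
    generate_cohort,
    generate_volume,
    phantom_spec_for,
)
from .volume import BoneMask, CtVolume

__all__ = [
    "random_test_volume",
    "mip_oracle_study",
    "calibration_recovery_study",
    "localization_study",
    "growth_study",
    "null_study",
]


# ---------------------------------------------------------------------------
# MIP vs brute-force reference

def random_test_volume(rng: np.random.Generator, max_side: int = 20):
    """A small random volume with an ellipsoidal random mask, for oracle checks.

    Spacings and ellipsoid parameters are drawn as generic floats so that
    ray samples essentially never fall exactly on voxel-boundary midpoints;
    nearest-voxel decisions are then identical between implementations.
    """
    shape = tuple(int(rng.integers(10, max_side + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.6, 1.3)) for _ in range(3))
    extent = np.asarray(shape) * np.asarray(spacing)
    mask = np.zeros(shape, dtype=bool)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    for _ in range(int(rng.integers(1, 3))):
        center = rng.uniform(0.25, 0.75, size=3) * extent
        radii = rng.uniform(0.15, 0.4, size=3) * extent
        mask |= (
            ((gx - center[0]) / radii[0]) ** 2
            + ((gy - center[1]) / radii[1]) ** 2
            + ((gz - center[2]) / radii[2]) ** 2
        ) <= 1.0
    if not mask.any():
        mask[tuple(n // 2 for n in shape)] = True
    hu = rng.normal(500.0, 300.0, size=shape)
    return CtVolume(hu, spacing), BoneMask(mask)


def mip_oracle_study(n_volumes: int = 20, seed: int = 0, max_side: int = 20) -> pd.DataFrame:
    """Compare ``project_mip`` with the per-pixel reference on random volumes.

    Views are random tilts of the proximal frame (0–90°) with random MIP
    depths (1–3 mm).  Returns one row per volume with the maximum absolute
    pixel discrepancy and a surface-mask agreement flag.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_volumes):
        vol, mask = random_test_volume(rng, max_side=max_side)
        tilt = float(rng.uniform(0.0, 90.0))
        depth = float(rng.uniform(1.0, 3.0))
        view = make_view(f"tilt{tilt:.0f}", tilt, mip_depth=depth)
        fast = project_mip(vol, mask, view)
        slow = mip_bruteforce(vol, mask, view)
        same_surface = bool(np.array_equal(fast.surface_mask, slow.surface_mask))
        if same_surface and fast.surface_mask.any():
            diff = np.abs(
                fast.values_hu[fast.surface_mask] - slow.values_hu[slow.surface_mask]
            )
            max_err = float(diff.max())
        else:
            max_err = np.inf
        rows.append(
            {
                "volume": i,
                "shape": vol.shape,
                "tilt_deg": tilt,
                "mip_depth": depth,
                "surface_px": int(fast.surface_mask.sum()),
                "surface_match": same_surface,
                "max_abs_err_hu": max_err,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration recovery

def calibration_recovery_study(
    n_seeds: int = 20, seed: int = 0, spec: SyntheticSpec | None = None
) -> dict:
    """Recover the true HU→density line from the synthetic phantom.

    Noise-free: slope/intercept must match the configured truth to a tiny
    relative tolerance.  Noisy (default 10 HU SD): relative slope error is
    tracked over ``n_seeds`` independent scans.
    """
    base = spec if spec is not None else default_spec()
    slope_true, intercept_true = base.true_calibration
    phantom = phantom_spec_for(base)

    clean = replace(base, noise_sd=0.0, rng_seed=seed)
    vol, _, _ = generate_volume(clean)
    fit0 = fit_calibration(vol, phantom)
    clean_slope_err = abs(fit0.slope - slope_true) / abs(slope_true)
    clean_intercept_err = abs(fit0.intercept - intercept_true)
    # round trip: noise-free insert ROI means must map back to the nominals
    roundtrip_err = float(
        np.max(np.abs(apply_calibration(fit0.mean_hu, fit0) - fit0.densities))
    )

    slope_errs = []
    for k in range(n_seeds):
        noisy = replace(base, noise_sd=10.0, rng_seed=seed + 1000 + k)
        vol, _, _ = generate_volume(noisy)
        fit = fit_calibration(vol, phantom)
        slope_errs.append(abs(fit.slope - slope_true) / abs(slope_true))
    roi_sizes = [int(np.asarray(roi).sum()) for _, roi in phantom.inserts]
    return {
        "clean_slope_rel_err": float(clean_slope_err),
        "clean_intercept_abs_err": float(clean_intercept_err),
        "clean_roundtrip_max_err": roundtrip_err,
        "noisy_slope_rel_errs": np.asarray(slope_errs),
        "noisy_slope_rel_err_max": float(np.max(slope_errs)),
        "min_roi_voxels": min(roi_sizes),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Hotspot localization

def localization_study(
    n_seeds: int = 10,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
    min_area: int = 3,
) -> pd.DataFrame:
    """Detect density maxima and measure grid-centroid error against the
    generator's hotspot anchors.

    For every seed, view and visible hotspot, the anchor is projected into
    the view frame, mapped through the detection grid frame, and paired
    with the nearest detected region.  One row per (seed, view, hotspot).
    """
    base = spec if spec is not None else default_spec()
    phantom = phantom_spec_for(base)
    views = default_views()
    rows = []
    for k in range(n_seeds):
        sp = replace(base, rng_seed=seed + k)
        vol, mask, gt = generate_volume(sp)
        fit = fit_calibration(vol, phantom)
        for view in views:
            an = analyze_scan(vol, mask, view, fit, min_area=min_area)
            centroids = [r.centroid_grid for r in an.maxima]
            for loc in gt.view_locations[view.name]:
                r, c = an.densitogram.plane_to_pixel(loc.u_mm, loc.v_mm)
                gx, gy = an.frame.pixel_to_grid(
                    float(np.clip(r, an.frame.row_min, an.frame.row_max)),
                    float(np.clip(c, an.frame.col_min, an.frame.col_max)),
                )
                if centroids:
                    dists = [np.hypot(x - gx, y - gy) for x, y in centroids]
                    err = float(min(dists))
                else:
                    err = np.inf
                rows.append(
                    {
                        "seed": seed + k,
                        "view": view.name,
                        "hotspot": loc.hotspot_index,
                        "truth_x": gx,
                        "truth_y": gy,
                        "n_regions": len(centroids),
                        "centroid_err_grid": err,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Longitudinal contrast and type-I error

def growth_study(
    n_seeds: int = 20,
    seed: int = 0,
    n_subjects: int = 10,
    growth_factor: float = 1.15,
    noise_sd: float = 5.0,
    spec: SyntheticSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeat the two-time-point study on growing cohorts.

    Returns one row per (seed, view) with: whether every subject's t2
    exceeded t1 for mean density / max density / MAR, the cohort-level
    paired-test p-values, and the Hotelling p of the maxima-location test.
    """
    base = spec if spec is not None else default_spec()
    base = replace(base, noise_sd=noise_sd)
    phantom = phantom_spec_for(base)
    views = default_views()
    rows = []
    for k in range(n_seeds):
        cohort = generate_cohort(n_subjects, growth_factor, base, seed + 7919 * k)
        metrics = []
        for sid, tp, scan in cohort.scans():
            fit = fit_calibration(scan.volume, phantom)
            for view in views:
                an = analyze_scan(scan.volume, scan.mask, view, fit)
                metrics.append(an.metrics)
        cmp = compare_paired(metrics, alpha=alpha)
        df = cmp.table.set_index(["view", "metric"])
        piv = {
            (m.view, m.timepoint, m.subject_id): m for m in metrics
        }
        for view in views:
            per_metric = {}
            for metric in ("mean_density", "max_density", "mar_pct"):
                vals1 = [
                    getattr(piv[(view.name, "t1", s.subject_id)], metric)
                    for s in cohort.subjects
                ]
                vals2 = [
                    getattr(piv[(view.name, "t2", s.subject_id)], metric)
                    for s in cohort.subjects
                ]
                per_metric[metric] = {
                    "all_increase": bool(np.all(np.asarray(vals2) > np.asarray(vals1))),
                    "p": float(df.loc[(view.name, metric), "p_value"]),
                }
            coord = cmp.coordinates.set_index("view").loc[view.name]
            rows.append(
                {
                    "seed": seed + 7919 * k,
                    "view": view.name,
                    "mean_increase_all": per_metric["mean_density"]["all_increase"],
                    "max_increase_all": per_metric["max_density"]["all_increase"],
                    "mar_increase_all": per_metric["mar_pct"]["all_increase"],
                    "p_mean": per_metric["mean_density"]["p"],
                    "p_max": per_metric["max_density"]["p"],
                    "p_mar": per_metric["mar_pct"]["p"],
                    "coord_p": float(coord["hotelling_p"]),
                    "coord_n": int(coord["n"]),
                }
            )
    return pd.DataFrame(rows)


def null_study(
    n_cohorts: int = 1000,
    seed: int = 0,
    n_subjects: int = 10,
    noise_sd: float = 10.0,
    alpha: float = 0.05,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Type-I error of the paired test on null cohorts (growth factor 1.0).

    Uses the compact synthetic anatomy and a single (proximal) view with
    the mean surface density as the tested metric, so that thousands of
    full generator→projection→calibration replicates stay tractable.
    """
    base = spec if spec is not None else compact_spec()
    base = replace(base, noise_sd=noise_sd)
    phantom = phantom_spec_for(base)
    view = default_views()[0]
    from scipy import stats as sstats

    pvals = np.empty(n_cohorts)
    for k in range(n_cohorts):
        cohort = generate_cohort(n_subjects, 1.0, base, seed + 104729 + k,
                                 with_ground_truth=False)
        means = {"t1": [], "t2": []}
        for subj in cohort.subjects:
            for tp, scan in (("t1", subj.t1), ("t2", subj.t2)):
                fit = fit_calibration(scan.volume, phantom)
                dg = project_mip(scan.volume, scan.mask, view)
                dens = apply_calibration(dg.values_hu[dg.surface_mask], fit)
                means[tp].append(float(dens.mean()))
        t, p = sstats.ttest_rel(means["t2"], means["t1"])
        pvals[k] = p
    rate = float(np.mean(pvals < alpha))
    se = np.sqrt(alpha * (1 - alpha) / n_cohorts)
    return {
        "rejection_rate": rate,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
        "binomial_ci95": (alpha - 1.96 * se, alpha + 1.96 * se),
        "pvals": pvals,
    }
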