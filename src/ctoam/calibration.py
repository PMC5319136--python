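"""HU → mg hydroxyapatite/cm³ calibration from a density-reference phantom.

A calibration phantom with inserts of known hydroxyapatite-equivalent
density is scanned together with the subject.  The mean HU inside each
insert ROI is regressed (ordinary least squares) against the nominal
densities, giving an affine map

    density [mg HA/cm³] = slope · HU + intercept

that converts attenuation to absolute bone-equivalent density and removes
inter-scan variability.  The ROI statistic is the arithmetic mean with no
HU thresholding: each ROI is a defined region of homogeneous material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InputError
from .volume import CtVolume

__all__ = ["PhantomSpec", "CalibrationFit", "fit_calibration", "apply_calibration"]


@dataclass
class PhantomSpec:
    """Phantom description: ``inserts`` is a list of (nominal density, ROI mask).

    ROI masks are binary 3D arrays aligned with the volume they will be
    measured in.  At least two inserts with distinct densities and disjoint,
    non-empty ROIs are required for a line fit.
    """

    inserts: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.inserts) < 2:
            raise InputError("phantom needs at least 2 inserts to fit a line")
        densities = [float(d) for d, _ in self.inserts]
        if len(set(densities)) != len(densities):
            raise InputError("phantom insert densities must be distinct")
        occupancy = None
        for d, roi in self.inserts:
            roi = np.asarray(roi).astype(bool)
            if not roi.any():
                raise InputError(f"insert ROI for density {d} is empty")
            occupancy = roi.astype(int) if occupancy is None else occupancy + roi
        if occupancy is not None and occupancy.max() > 1:
            raise InputError("phantom insert ROIs overlap")


@dataclass
class CalibrationFit:
    """Fitted affine HU→density map with regression diagnostics."""

    slope: float        # mg HA/cm³ per HU
    intercept: float    # mg HA/cm³
    r_squared: float
    residuals: np.ndarray  # nominal − predicted, one per insert, mg HA/cm³
    mean_hu: np.ndarray    # per-insert mean HU used in the fit
    densities: np.ndarray  # nominal insert densities

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise DegenerateFitError(f"calibration slope {self.slope} is degenerate")


def fit_calibration(volume: CtVolume, phantom: PhantomSpec) -> CalibrationFit:
    """OLS line through (mean ROI HU, nominal density) pairs.

    Raises
    ------
    InputError
        If an ROI extends outside the volume or is empty.
    DegenerateFitError
        If all inserts have identical mean HU (vertical line) or the fitted
        slope is zero.
    """
    means, densities = [], []
    for density, roi in phantom.inserts:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != volume.shape:
            raise InputError(
                f"ROI shape {roi.shape} does not match volume shape {volume.shape}"
            )
        means.append(float(volume.voxels[roi].mean()))
        densities.append(float(density))
    means_arr = np.asarray(means)
    dens_arr = np.asarray(densities)
    if np.ptp(means_arr) == 0:
        raise DegenerateFitError("all inserts have identical mean HU; cannot fit line")
    res = stats.linregress(means_arr, dens_arr)
    residuals = dens_arr - (res.slope * means_arr + res.intercept)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=residuals,
        mean_hu=means_arr,
        densities=dens_arr,
    )


def apply_calibration(value_hu, fit: CalibrationFit):
    """Convert HU to mg HA/cm³, elementwise; shape (and NaNs) preserved."""
    return fit.slope * np.asarray(value_hu, dtype=float) + fit.intercept
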