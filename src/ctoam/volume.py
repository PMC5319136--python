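"""CT volume and bone-mask containers plus NIfTI/DICOM I/O.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` along the world axes ``(x, y, z)``:

* ``x`` — medial→lateral,
* ``y`` — the horizontal axis the dorsal view looks along,
* ``z`` — distal→proximal (slice axis).

The world position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
in millimetres.  NIfTI files are written with a diagonal affine carrying the
spacing and origin, so volumes round-trip through ``nibabel`` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = ["CtVolume", "BoneMask", "save_nifti", "load_volume", "load_mask"]


@dataclass
class CtVolume:
    """A reconstructed CT volume in Hounsfield units.

    Parameters
    ----------
    voxels:
        3D float array of HU values, axis order ``(x, y, z)``.
    spacing:
        Voxel spacing in mm per axis; all entries strictly positive.
    origin:
        World position of voxel ``(0, 0, 0)`` in mm.
    subject_id, timepoint:
        Optional provenance labels (timepoint is ``"t1"`` or ``"t2"`` in a
        longitudinal cohort).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InputError("CT volume must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"voxel spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_extent(self) -> np.ndarray:
        """(2, 3) array: world coordinates of the first and last voxel centres."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi])


@dataclass
class BoneMask:
    """Binary bone mask congruent with a :class:`CtVolume`."""

    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or self.data.size == 0:
            raise InputError("bone mask must be a non-empty 3D array")
        if not self.data.any():
            raise InputError("bone mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def check_congruent(self, volume: CtVolume) -> None:
        if self.shape != volume.shape:
            raise InputError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(path: str | Path, array: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D array as NIfTI with spacing/origin encoded in the affine."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(array), _affine(spacing, origin))
    nib.save(img, str(path))


def _read_array(path: str | Path):
    """Return (array, spacing, origin) from a NIfTI file or a DICOM directory."""
    path = Path(path)
    if path.is_dir():  # DICOM series
        import SimpleITK as sitk

        reader = sitk.ImageSeriesReader()
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path)))
        img = reader.Execute()
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
        return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(np.abs(np.diag(aff)[:3]))
    origin = tuple(aff[:3, 3])
    return arr, spacing, origin


def load_volume(path: str | Path, subject_id: str | None = None,
                timepoint: str | None = None) -> CtVolume:
    """Load a CT volume from a NIfTI file or DICOM series directory."""
    arr, spacing, origin = _read_array(path)
    return CtVolume(arr.astype(float), spacing, origin, subject_id, timepoint)


def load_mask(path: str | Path) -> BoneMask:
    """Load a binary bone mask from NIfTI (non-zero voxels are foreground)."""
    arr, _, _ = _read_array(path)
    return BoneMask(arr > 0)
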