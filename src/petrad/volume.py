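"""PET volume IO, SUV conversion, and routine PET variables.

A :class:`PETVolume` holds a 3D grid of voxel values indexed ``[x, y, z]``
(``z`` is the slice axis), its physical geometry, and optional scanner
metadata.  Values are body-weight standardized uptake values (SUV,
dimensionless) once calibrated; volumes loaded from raw activity data carry
``is_suv=False`` and must pass through :func:`convert_to_suv` before any
downstream analysis.

Physical coordinates follow ``origin + index * spacing`` with 0-based voxel
indices.  Masks live on the PET grid; no resampling is performed anywhere in
the package (voxel sizes are deliberately left as acquired).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

FDG_HALF_LIFE_MIN = 109.771  # 18F physical half-life


@dataclass(frozen=True)
class ScannerMeta:
    """Acquisition metadata used for scanner-invariance analyses."""

    manufacturer: str = ""
    model: str = ""
    slice_thickness: float = float("nan")  # mm
    matrix_rows: int = 1
    matrix_cols: int = 1

    def __post_init__(self) -> None:
        if self.matrix_rows < 1 or self.matrix_cols < 1:
            raise ValueError("matrix dimensions must be >= 1")


@dataclass
class PETVolume:
    """A 3D PET volume with geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Voxel values, SUV if ``is_suv`` else raw activity concentration
        (kBq/ml).
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    scanner_meta : ScannerMeta, optional
    is_suv : bool
        Whether voxel values are already calibrated SUV.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scanner_meta: ScannerMeta = field(default_factory=ScannerMeta)
    is_suv: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.is_suv and self.voxels.min() < 0:
            raise ValueError("SUV volumes must be non-negative")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class SUVStats:
    """Routine PET variables of one lesion."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv: float  # ml
    tlg: float  # SUV*ml, = suv_mean * mtv

    def as_row(self) -> dict:
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "suv_peak": self.suv_peak,
            "mtv_ml": self.mtv,
            "tlg": self.tlg,
        }


# ---------------------------------------------------------------------------
# IO


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def save_nifti(volume: PETVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI; voxel order (x, y, z) maps to (i, j, k)."""
    import nibabel as nib

    img = nib.Nifti1Image(
        volume.voxels.astype(np.float64),
        _affine_from_geometry(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def save_mask_nifti(mask: np.ndarray, spacing, path: str | os.PathLike, origin=(0.0, 0.0, 0.0)) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine_from_geometry(spacing, origin))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, os.fspath(path))


def load_volume(path: str | os.PathLike, format: str | None = None) -> PETVolume:
    """Load a PET volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"``, ``"dicom_series"`` or ``None`` (inferred:
    directories are DICOM series, files are NIfTI).  NIfTI volumes are
    assumed calibrated (SUV); DICOM series are returned in SUV only when the
    ``Units`` tag says so, otherwise as raw activity with ``is_suv=False``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: str) -> PETVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError("NIfTI header lacks valid voxel spacing")
    origin = tuple(np.asarray(img.affine)[:3, 3])
    return PETVolume(data, tuple(float(z) for z in zooms), origin)


def _load_dicom_series(dirpath: str, spacing_tol: float = 0.01) -> PETVolume:
    """Read a single-frame PET DICOM series (one file per slice)."""
    import pydicom

    files = sorted(
        os.path.join(dirpath, f)
        for f in os.listdir(dirpath)
        if not f.startswith(".")
    )
    if not files:
        raise ValueError(f"no DICOM files in {dirpath}")
    slices = [pydicom.dcmread(f) for f in files]

    def zpos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        raise ValueError("DICOM slice lacks ImagePositionPatient")

    slices.sort(key=zpos)
    zs = np.array([zpos(s) for s in slices])
    if len(zs) < 2:
        raise ValueError("DICOM series must contain at least 2 slices")
    steps = np.diff(zs)
    if steps.min() <= 0:
        raise ValueError("duplicate or unordered slice positions")
    if (steps.max() - steps.min()) > spacing_tol * steps.mean():
        raise ValueError(
            "inconsistent slice spacing (possible missing slice); "
            f"steps range {steps.min():.4g}-{steps.max():.4g} mm"
        )
    first = slices[0]
    if "PixelSpacing" not in first:
        raise ValueError("DICOM series lacks PixelSpacing")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    shapes = {s.pixel_array.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError("inconsistent slice matrix sizes")

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + inter)
    # pixel_array rows are y, columns are x; reorder to [x, y, z]
    vol = np.stack(planes, axis=-1).transpose(1, 0, 2)

    units = str(getattr(first, "Units", "")).upper()
    is_suv = units in ("GML", "SUV")
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    meta = ScannerMeta(
        manufacturer=str(getattr(first, "Manufacturer", "")),
        model=str(getattr(first, "ManufacturerModelName", "")),
        slice_thickness=float(getattr(first, "SliceThickness", steps.mean())),
        matrix_rows=int(first.Rows),
        matrix_cols=int(first.Columns),
    )
    return PETVolume(vol, (col_sp, row_sp, float(steps.mean())), origin, meta, is_suv=is_suv)


# ---------------------------------------------------------------------------
# SUV calibration


def convert_to_suv(
    activity_volume: PETVolume,
    injected_dose_mbq: float,
    body_weight_kg: float,
    decay_interval_min: float = 0.0,
    half_life_min: float = FDG_HALF_LIFE_MIN,
) -> PETVolume:
    """Convert an activity-concentration volume (kBq/ml) to body-weight SUV.

    SUV = concentration / (decay-corrected injected dose [kBq] / body weight
    [kg]), with the dose decayed from injection to scan start over
    ``decay_interval_min``.  Lean-body-mass and BSA variants are out of scope.
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    dose_kbq = injected_dose_mbq * 1000.0
    decayed = dose_kbq * 2.0 ** (-decay_interval_min / half_life_min)
    suv = activity_volume.voxels / (decayed / body_weight_kg)
    return replace(activity_volume, voxels=np.clip(suv, 0.0, None), is_suv=True)


# ---------------------------------------------------------------------------
# Routine PET variables


def _sphere_kernel(spacing, kernel_ml: float) -> np.ndarray:
    """Binary sphere of ~``kernel_ml`` ml built on the voxel grid.

    The radius is the analytic sphere radius for the requested volume; a
    voxel belongs to the kernel when its center lies within that radius
    (center voxel always included).
    """
    r_mm = (3.0 * kernel_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half = [max(1, int(math.floor(r_mm / s))) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dist2 = (
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    kern = dist2 <= r_mm**2
    kern[half[0], half[1], half[2]] = True
    return kern


def compute_suv_stats(volume: PETVolume, mask: np.ndarray, peak_kernel_ml: float = 1.0) -> SUVStats:
    """SUVmax/mean/peak, MTV and TLG of one lesion.

    SUVpeak is the maximum, over lesion voxels, of the mean SUV inside a
    ~1 ml sphere centered at the voxel (EANM-style); sphere voxels falling
    outside the image are dropped from the mean.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    if not volume.is_suv:
        raise ValueError("volume must be in SUV; run convert_to_suv first")

    vals = volume.voxels[mask]
    suv_max = float(vals.max())
    suv_mean = float(vals.mean())
    mtv = n * volume.voxel_volume_ml
    tlg = suv_mean * mtv

    kern = _sphere_kernel(volume.spacing, peak_kernel_ml).astype(np.float64)
    num = ndimage.convolve(volume.voxels, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(volume.voxels), kern, mode="constant", cval=0.0)
    sphere_mean = num / den
    suv_peak = float(sphere_mean[mask].max())
    return SUVStats(suv_max, suv_mean, suv_peak, mtv, tlg)
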