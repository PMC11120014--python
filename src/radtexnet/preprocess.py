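"""Loading and preprocessing of chest-CT volumes.

Volumes are held as plain numpy arrays in Hounsfield units (HU) with axis
order ``(x, y, z)``; ``z`` is the axial slice index and the axial plane is
``(x, y)``.  Preprocessing follows the usual radiomics recipe for diffuse
lung disease: center-crop the axial plane to focus on the lungs (no
segmentation, no region of interest), clip to a lung window, and resample
to a fixed grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import nibabel as nib
import pydicom
from scipy import ndimage


@dataclass
class CTVolume:
    """A 3D CT image with voxel spacing and an optional binary label.

    ``label`` follows the convention positive = pulmonary sarcoidosis (1),
    negative = lung-cancer-like (0).
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"empty axis in shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.label is not None:
            if int(self.label) not in (0, 1):
                raise ValueError(f"label must be 0, 1 or None, got {self.label}")
            self.label = int(self.label)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.voxels.shape)


@dataclass
class PreprocessSpec:
    """Target grid, HU clipping window and axial center-crop fraction."""

    target_shape: Tuple[int, int, int] = (256, 256, 64)
    window: Tuple[float, float] = (-1000.0, 400.0)
    crop_fraction: float = 0.75

    def __post_init__(self) -> None:
        self.target_shape = tuple(int(d) for d in self.target_shape)
        if len(self.target_shape) != 3 or any(d < 8 for d in self.target_shape):
            raise ValueError(f"target dims must be >= 8, got {self.target_shape}")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window low must be < high, got {self.window}")
        self.window = (float(lo), float(hi))
        if not 0 < self.crop_fraction <= 1:
            raise ValueError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")


def load_volume(path: str, format: str = "nifti") -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Returns voxels in HU (DICOM rescale slope/intercept applied) with
    spacing taken from the header, axis order (x, y, z).
    """
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


def _load_nifti(path: str) -> CTVolume:
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several I/O error types
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path!r} is not a 3D image (ndim={data.ndim})")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(voxels=data, spacing=tuple(float(z) for z in zooms))


def save_volume(vol: CTVolume, path: str) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine built from spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def _load_dicom_dir(path: str) -> CTVolume:
    if not os.path.isdir(path):
        raise IOError(f"{path!r} is not a directory")
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM slices under {path!r}")
    # Sort slices along the normal of the image orientation (fall back to
    # InstanceNumber when position tags are absent).
    if hasattr(slices[0], "ImagePositionPatient"):
        orient = np.asarray(
            getattr(slices[0], "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]),
            dtype=float,
        )
        normal = np.cross(orient[:3], orient[3:])
        slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    else:
        slices.sort(key=lambda s: int(getattr(s, "InstanceNumber", 0)))

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    stack = np.stack(planes, axis=-1)  # (rows, cols, z) = (y, x, z)
    voxels = np.transpose(stack, (1, 0, 2))  # -> (x, y, z)

    first = slices[0]
    ps = getattr(first, "PixelSpacing", [1.0, 1.0])  # (row, col) = (y, x)
    if len(slices) > 1 and hasattr(first, "ImagePositionPatient"):
        p0 = np.asarray(slices[0].ImagePositionPatient, float)
        p1 = np.asarray(slices[1].ImagePositionPatient, float)
        dz = float(np.linalg.norm(p1 - p0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    if dz <= 0:
        dz = 1.0
    return CTVolume(voxels=voxels, spacing=(float(ps[1]), float(ps[0]), dz))


def _center_crop_axial(a: np.ndarray, fraction: float) -> np.ndarray:
    if fraction >= 1.0:
        return a
    out = a
    for axis in (0, 1):  # in-plane axes only
        n = out.shape[axis]
        keep = max(2, int(round(n * fraction)))
        start = (n - keep) // 2
        sl = [slice(None)] * 3
        sl[axis] = slice(start, start + keep)
        out = out[tuple(sl)]
    return out


def preprocess_volume(v: CTVolume, spec: Optional[PreprocessSpec] = None) -> CTVolume:
    """Center-crop axially, clip to the lung window, and resample.

    The clip is applied before trilinear resampling so interpolation cannot
    ring outside the window.  Output shape is exactly ``spec.target_shape``
    and the label is carried through unchanged.
    """
    spec = spec or PreprocessSpec()
    a = np.asarray(v.voxels, dtype=np.float64)
    if any(d < 2 for d in a.shape):
        raise ValueError(f"input must be >= 2 voxels on every axis, got {a.shape}")
    a = _center_crop_axial(a, spec.crop_fraction)
    lo, hi = spec.window
    a = np.clip(a, lo, hi)
    factors = [t / s for t, s in zip(spec.target_shape, a.shape)]
    out = ndimage.zoom(a, factors, order=1, mode="nearest", grid_mode=True)
    # grid_mode zoom can be off by one voxel on awkward ratios; enforce shape.
    out = _fit_to_shape(out, spec.target_shape)
    new_spacing = tuple(
        sp * s / t for sp, s, t in zip(v.spacing, a.shape, spec.target_shape)
    )
    return CTVolume(voxels=out, spacing=new_spacing, label=v.label)


def _fit_to_shape(a: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    slices = tuple(slice(0, min(s, t)) for s, t in zip(a.shape, shape))
    a = a[slices]
    pads = [(0, t - s) for s, t in zip(a.shape, shape)]
    if any(p[1] for p in pads):
        a = np.pad(a, pads, mode="edge")
    return a


def minmax_normalize(a: np.ndarray) -> np.ndarray:
    """Map an array linearly onto [0, 1]; constant arrays map to zeros."""
    a = np.asarray(a, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("array contains NaN or Inf")
    lo = a.min()
    hi = a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)
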