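"""Reading and writing volumes, masks and label maps.

NIfTI-1 is the primary on-disk format (via nibabel); volumes are reoriented
to RAS on load so the third index axis is craniocaudal. A DICOM PET series
is accepted as an optional input (via pydicom) with rescale slope/intercept
applied; slices must share orientation and in-plane spacing. ROI boxes and
seeds come from a small JSON config.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import GeometryError, InputError, LesionROI, SUVVolume, TumorMask, make_roi
from .deciles import LayerLabelMap

__all__ = [
    "load_volume",
    "save_volume",
    "save_mask",
    "save_label_map",
    "load_roi_config",
]


def _affine(volume: SUVVolume) -> np.ndarray:
    aff = np.diag(list(volume.spacing) + [1.0])
    aff[:3, 3] = volume.origin
    return aff


def load_volume(path: str | Path, format: str = "nifti") -> SUVVolume:
    """Load a PET volume in SUV units from NIfTI or a DICOM series directory.

    NIfTI volumes are reoriented to closest-canonical RAS so that axis 2 is
    craniocaudal. For DICOM, ``path`` is a directory of slices of one
    series; rescale slope/intercept are applied and slices are stacked along
    the normal. Values are returned unchanged (assumed already in SUV); use
    :func:`halopet.core.activity_to_suv` for Bq/mL data.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    if format == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise InputError(f"cannot parse NIfTI file {path}: {exc}") from exc
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if data.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return SUVVolume(
            values=data, spacing=tuple(float(z) for z in zooms), axcodes=("R", "A", "S"), origin=origin
        )
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise InputError(f"unknown format {format!r}")


def _load_dicom_series(directory: Path) -> SUVVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise InputError(f"no files in DICOM directory {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise InputError(f"cannot parse DICOM file {f}: {exc}") from exc
        slices.append(ds)
    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 6)) for s in slices}
    spacings = {tuple(np.round(np.asarray(s.PixelSpacing, float), 6)) for s in slices}
    if len(orientations) != 1 or len(spacings) != 1:
        raise GeometryError("DICOM slices differ in orientation or pixel spacing")
    orient = np.asarray(slices[0].ImageOrientationPatient, float)
    normal = np.cross(orient[:3], orient[3:])
    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    positions = [float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)) for s in slices]
    steps = np.diff(positions)
    if len(steps) and (np.ptp(steps) > 1e-3 or steps[0] <= 0):
        raise GeometryError("DICOM slice spacing is not uniform")
    dz = float(steps[0]) if len(steps) else float(getattr(slices[0], "SliceThickness", 1.0))
    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # stack as (row=x, col=y, slice=z); craniocaudal along the normal
    data = np.stack(planes, axis=-1)
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return SUVVolume(values=data, spacing=(dx, dy, dz), axcodes=("R", "A", "S"), origin=origin)


def save_volume(volume: SUVVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float64)."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: TumorMask, path: str | Path, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a binary tumor mask as an integer NIfTI aligned to its grid."""
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = origin
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def save_label_map(labels: LayerLabelMap, spacing, path: str | Path) -> None:
    """Write a decile label map as an integer NIfTI for visual inspection."""
    aff = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(labels.labels.astype(np.int16), aff)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_roi_config(path: str | Path, volume: SUVVolume) -> LesionROI:
    """Build a :class:`LesionROI` from a JSON config of box bounds and seed.

    Expected keys: ``box`` as ``[[i0, i1], [j0, j1], [k0, k1]]`` (inclusive,
    0-based) and optionally ``seed`` as ``[i, j, k]``.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if "box" not in cfg:
        raise InputError(f"ROI config {path} lacks a 'box' entry")
    box = tuple((int(lo), int(hi)) for lo, hi in cfg["box"])
    seed = tuple(int(v) for v in cfg["seed"]) if "seed" in cfg else None
    return make_roi(volume, box, seed=seed)
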