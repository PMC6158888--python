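"""Core data model: SUV volumes, lesion regions of interest, tumor masks.

All geometry is kept in millimetres on a regular voxel grid. The third index
axis is the craniocaudal (z) axis by convention; volumes loaded from disk are
reoriented accordingly (see :mod:`halopet.io`). Voxel indexing is 0-based and
bounding boxes are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUVVolume",
    "LesionROI",
    "TumorMask",
    "activity_to_suv",
    "make_roi",
    "HalopetError",
    "InputError",
    "GeometryError",
    "ParameterError",
    "DetectionError",
]


class HalopetError(Exception):
    """Base class for all package errors."""


class InputError(HalopetError):
    """Missing, corrupt, or inconsistent input data."""


class GeometryError(HalopetError):
    """Inconsistent voxel geometry (spacing, orientation, bounds)."""


class ParameterError(HalopetError):
    """Invalid user-supplied parameter."""


class DetectionError(HalopetError):
    """The halo/background detection could not be carried out."""


@dataclass
class SUVVolume:
    """A 3-D scalar field of standardized uptake values.

    Parameters
    ----------
    values
        3-D array of body-weight SUV (dimensionless), all finite and >= 0.
    spacing
        Per-axis voxel edge length in mm, strictly positive.
    axcodes
        Anatomical orientation of the three index axes (RAS-style letters).
        The third axis must be craniocaudal (``S`` or ``I``).
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.65, 2.65, 2.65)
    axcodes: tuple[str, str, str] = ("R", "A", "S")
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("SUV volume contains non-finite values")
        if np.any(self.values < 0):
            raise InputError("SUV volume contains negative values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.axcodes[2] not in ("S", "I"):
            raise GeometryError(
                f"third axis must be craniocaudal (S/I), got axcodes={self.axcodes}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionROI:
    """A lesion region of interest: inclusive voxel box, seed and SUVmax.

    ``box`` is ``((i0, i1), (j0, j1), (k0, k1))`` with inclusive 0-based
    bounds. ``suvmax`` is the maximum SUV inside the box and ``suvmax_voxel``
    the voxel attaining it (ties broken by lowest C-order linear index).
    """

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    seed: tuple[int, int, int]
    suvmax: float
    suvmax_voxel: tuple[int, int, int]

    def contains(self, voxel: tuple[int, int, int]) -> bool:
        return all(lo <= v <= hi for v, (lo, hi) in zip(voxel, self.box))

    def box_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi + 1) for lo, hi in self.box)


@dataclass
class TumorMask:
    """Binary tumor segmentation on the grid of its source volume.

    The mask is a single 26-connected component containing ``seed`` (or empty
    when the seed falls below the threshold); every mask voxel has
    SUV >= ``threshold_suv``.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    threshold_suv: float
    seed: tuple[int, int, int]
    method: str = ""
    threshold_percent: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return not self.mask.any()


def activity_to_suv(
    activity: np.ndarray,
    injected_dose_mbq: float,
    body_weight_kg: float,
    spacing: tuple[float, float, float] = (2.65, 2.65, 2.65),
    **volume_kwargs,
) -> SUVVolume:
    """Convert an activity-concentration image (Bq/mL) to body-weight SUV.

    SUV = activity / (injected dose / body weight), with dose in Bq and
    weight in g, so that a uniform distribution of the dose over the body
    yields SUV = 1. The dose must already be decay-corrected to scan time.
    """
    if injected_dose_mbq <= 0:
        raise ParameterError(f"injected dose must be positive, got {injected_dose_mbq} MBq")
    if body_weight_kg <= 0:
        raise ParameterError(f"body weight must be positive, got {body_weight_kg} kg")
    dose_bq = injected_dose_mbq * 1e6
    weight_g = body_weight_kg * 1e3
    suv = np.asarray(activity, dtype=np.float64) * (weight_g / dose_bq)
    return SUVVolume(values=suv, spacing=spacing, **volume_kwargs)


def make_roi(
    volume: SUVVolume,
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    seed: tuple[int, int, int] | None = None,
) -> LesionROI:
    """Build a :class:`LesionROI` over ``box``, computing SUVmax and seed.

    When ``seed`` is omitted it defaults to the SUVmax voxel. Ties in the
    maximum are broken toward the lowest linear index, which makes the seed
    deterministic.
    """
    box = tuple((int(lo), int(hi)) for lo, hi in box)
    for ax, (lo, hi) in enumerate(box):
        if lo < 0 or hi >= volume.shape[ax]:
            raise GeometryError(f"box {box} exceeds volume shape {volume.shape} on axis {ax}")
        if hi < lo:
            raise ParameterError(f"box has zero extent on axis {ax}: {box}")
    sub = volume.values[tuple(slice(lo, hi + 1) for lo, hi in box)]
    flat = int(np.argmax(sub))  # first occurrence = lowest linear index
    local = np.unravel_index(flat, sub.shape)
    suvmax_voxel = tuple(int(lo + o) for (lo, _), o in zip(box, local))
    suvmax = float(sub.max())
    if seed is None:
        seed = suvmax_voxel
    else:
        seed = tuple(int(s) for s in seed)
        if not all(lo <= s <= hi for s, (lo, hi) in zip(seed, box)):
            raise ParameterError(f"seed {seed} outside box {box}")
    return LesionROI(box=box, seed=seed, suvmax=suvmax, suvmax_voxel=suvmax_voxel)
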