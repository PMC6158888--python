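"""Digital PET phantoms: elongated hypermetabolic lesions with known truth.

The generator emulates an FDG-avid esophageal lesion: a plateau of uptake
``S`` over a uniform background ``B`` on an isotropic 2.65 mm grid, blurred
by an isotropic Gaussian point-spread function (partial-volume effect) and
optionally degraded with additive Gaussian noise. The exact pre-blur voxel
mask is retained as ground truth, standing in for the pathologic reference
length.

Shapes: a ``capsule`` is a cylinder along z with hemispherical end caps
(total z extent = requested length); when the requested length does not
exceed the diameter the capsule degenerates to a prolate spheroid. An
``ellipsoid`` uses semi-axes length/2 and diameter/2 directly. ``sphere``
is an ellipsoid with equal extents.

Noise is additive Gaussian, not a full Poisson sinogram simulation; that is
adequate to exercise threshold behaviour and is documented as a
simplification. Negative noise excursions are clipped at zero so volumes
remain valid SUV fields.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .core import GeometryError, LesionROI, SUVVolume, make_roi

__all__ = [
    "HotCore",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "roi_from_truth",
    "concentric_label_map",
]

#: FWHM-to-sigma conversion for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class HotCore:
    """A focal uptake perturbation inside the lesion (heterogeneity)."""

    offset_mm: tuple[float, float, float]  # relative to the lesion center
    amplitude: float  # added on top of the plateau, in SUV
    radius_mm: float = 6.0


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic lesion."""

    true_length_mm: float = 40.0
    diameter_mm: float = 20.0
    peak_suv: float = 10.0
    background_suv: float = 1.0
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.0
    voxel_mm: float = 2.65
    shape: str = "capsule"  # capsule | ellipsoid | sphere
    grid_shape: tuple[int, int, int] | None = None
    rng_seed: int = 0
    cores: tuple[HotCore, ...] = ()

    def __post_init__(self) -> None:
        if self.peak_suv <= self.background_suv or self.background_suv < 0:
            raise ValueError("require peak_suv > background_suv >= 0")
        if self.true_length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("lesion extents must be positive")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be >= 0")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["cores"] = [asdict(c) for c in self.cores]
        return d


@dataclass
class PhantomTruth:
    """Exact pre-blur ground truth of a phantom lesion."""

    mask: np.ndarray
    length_cm: float
    volume_ml: float

    def as_dict(self) -> dict:
        return {"length_cm": self.length_cm, "volume_ml": self.volume_ml}


def _auto_grid(spec: PhantomSpec, pad_mm: float) -> tuple[int, int, int]:
    def n(extent_mm: float) -> int:
        return int(math.ceil((extent_mm + 2 * pad_mm) / spec.voxel_mm)) | 1  # odd

    return (n(spec.diameter_mm), n(spec.diameter_mm), n(spec.true_length_mm))


def _lesion_indicator(spec: PhantomSpec, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize the lesion on the voxel grid, centered in the grid."""
    v = spec.voxel_mm
    center = (np.asarray(shape) - 1) / 2.0 * v
    ii, jj, kk = np.indices(shape)
    x = ii * v - center[0]
    y = jj * v - center[1]
    z = kk * v - center[2]
    r = spec.diameter_mm / 2.0
    hl = spec.true_length_mm / 2.0
    if spec.shape == "capsule" and spec.true_length_mm > spec.diameter_mm:
        # cylinder of half-length (hl - r) with hemispherical caps
        seg = hl - r
        dz = np.maximum(np.abs(z) - seg, 0.0)
        ind = x**2 + y**2 + dz**2 <= r**2
    elif spec.shape in ("capsule", "ellipsoid", "sphere"):
        ind = (x / r) ** 2 + (y / r) ** 2 + (z / hl) ** 2 <= 1.0
    else:
        raise ValueError(f"unknown phantom shape {spec.shape!r}")
    return ind


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, PhantomTruth]:
    """Generate one phantom volume and its exact ground truth.

    The pre-blur field is ``B + (S - B) * indicator`` plus any hot-core
    perturbations, convolved with an isotropic Gaussian of the requested
    FWHM, then degraded with seeded additive Gaussian noise. Identical specs
    (including the seed) give identical volumes.
    """
    # room for the PSF tails plus the background annulus used in detection
    pad_mm = 3.0 * spec.psf_fwhm_mm + 30.0
    shape = spec.grid_shape or _auto_grid(spec, pad_mm)
    if spec.grid_shape is not None:
        psf_margin = 2 * 3.0 * spec.psf_fwhm_mm
        needed = (
            spec.diameter_mm + psf_margin,
            spec.diameter_mm + psf_margin,
            spec.true_length_mm + psf_margin,
        )
        if any(n * spec.voxel_mm < req for n, req in zip(shape, needed)):
            raise GeometryError(
                f"grid {shape} too small for lesion of {spec.true_length_mm} mm "
                f"with {spec.psf_fwhm_mm} mm PSF"
            )
    ind = _lesion_indicator(spec, shape)
    if not ind.any():
        raise GeometryError("lesion rasterized to zero voxels; increase extents or grid")
    values = spec.background_suv + (spec.peak_suv - spec.background_suv) * ind.astype(np.float64)
    if spec.cores:
        v = spec.voxel_mm
        center = (np.asarray(shape) - 1) / 2.0 * v
        ii, jj, kk = np.indices(shape)
        for core in spec.cores:
            cx = center + np.asarray(core.offset_mm)
            d2 = (ii * v - cx[0]) ** 2 + (jj * v - cx[1]) ** 2 + (kk * v - cx[2]) ** 2
            values += core.amplitude * ((d2 <= core.radius_mm**2) & ind)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_mm
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)
    zs = np.nonzero(ind.any(axis=(0, 1)))[0]
    length_cm = (zs.max() - zs.min() + 1) * spec.voxel_mm / 10.0
    volume_ml = ind.sum() * spec.voxel_mm**3 / 1000.0
    truth = PhantomTruth(mask=ind, length_cm=float(length_cm), volume_ml=float(volume_ml))
    vol = SUVVolume(values=values, spacing=(spec.voxel_mm,) * 3)
    return vol, truth


def roi_from_truth(volume: SUVVolume, truth: PhantomTruth, pad_mm: float = 20.0) -> LesionROI:
    """Lesion ROI from the truth bounding box plus a padding margin.

    Stands in for a reader outlining the lesion on the workstation; the pad
    leaves room for the peritumoral rim while excluding far-field structures.
    """
    pad = [int(round(pad_mm / s)) for s in volume.spacing]
    box = []
    for ax in range(3):
        proj = np.nonzero(truth.mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
        lo = max(int(proj.min()) - pad[ax], 0)
        hi = min(int(proj.max()) + pad[ax], volume.shape[ax] - 1)
        box.append((lo, hi))
    return make_roi(volume, tuple(box))


def generate_cohort(
    n: int,
    s_range: tuple[float, float] = (3.0, 20.0),
    length_range_mm: tuple[float, float] = (10.0, 90.0),
    background_suv: float = 1.0,
    psf_fwhm_mm: float = 7.0,
    noise_sd: float = 0.15,
    rng_seed: int = 0,
) -> list[tuple[SUVVolume, PhantomTruth, PhantomSpec]]:
    """A reproducible cohort of lesions with varying uptake and length.

    Peak SUV is drawn log-uniformly over ``s_range`` (uptake spans an order
    of magnitude across patients) and true length uniformly over
    ``length_range_mm``, matching the 0.8-9.8 cm span of measured metabolic
    lengths in avid esophageal tumors. Identical seeds give identical
    cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        s = float(np.exp(rng.uniform(np.log(s_range[0]), np.log(s_range[1]))))
        length = float(rng.uniform(*length_range_mm))
        seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            true_length_mm=length,
            peak_suv=s,
            background_suv=background_suv,
            psf_fwhm_mm=psf_fwhm_mm,
            noise_sd=noise_sd,
            rng_seed=seed,
        )
        vol, truth = generate_phantom(spec)
        out.append((vol, truth, spec))
    return out


def concentric_label_map(
    bands_mm: list[tuple[int, float]],
    background_label: int,
    voxel_mm: float = 2.65,
    pad_mm: float = 10.0,
):
    """Hand-built concentric decile-label configuration for halo analysis.

    ``bands_mm`` lists ``(label, outer_radius_mm)`` from the hottest core
    outward: the first entry occupies all radii below its outer radius, each
    subsequent entry the annulus up to its own outer radius, and
    ``background_label`` fills the rest of the grid. This builds the
    idealized nested-shell geometry of a lesion with a prescribed halo
    thickness, for exercising the band-profile and halo-detection logic in
    isolation from any SUV field.

    Returns ``(LayerLabelMap, shell)`` where the shell covers the whole grid
    and the label map carries a nominal unit window.
    """
    from .deciles import LayerLabelMap, WindowSettings

    radii = [r for _, r in bands_mm]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("outer radii must be strictly increasing")
    extent = radii[-1] + pad_mm
    n = int(2 * math.ceil(extent / voxel_mm)) + 1
    c = (n - 1) / 2.0
    ii, jj, kk = np.indices((n, n, n))
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) * voxel_mm
    labels = np.full((n, n, n), background_label, dtype=np.int8)
    prev = 0.0
    for label, outer in bands_mm:
        labels[(r >= prev) & (r < outer)] = label
        prev = outer
    lmap = LayerLabelMap(
        labels=labels, window=WindowSettings(top=1.0), source_suvmax=1.0
    )
    shell = np.ones((n, n, n), dtype=bool)
    return lmap, shell
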