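"""Peritumoral halo layer (PHL) detection and adaptive tumor segmentation.

The PHL is the SUVmax-decile band lying between tumoral uptake and background
activity that shows an abrupt increase in layer thickness. Its inner edge
defines the adaptive tumor threshold: if the halo occupies the 20-30% layer,
the tumor threshold is 30% of SUVmax. The detection pipeline is:

1. restrict analysis to a shell around the lesion (``analysis_shell``),
2. measure per-decile band volumes, interface areas and thicknesses
   (``band_profile``),
3. locate the background decile from an annulus outside the shell
   (``background_band``),
4. walk inward from the background and pick the halo band by the abrupt
   thickness-increase criterion (``detect_phl``),
5. threshold and keep the seed's 26-connected component (``segment``).

Everything is deterministic: identical inputs give identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DetectionError, LesionROI, ParameterError, SUVVolume, TumorMask
from .deciles import LayerLabelMap, decile_label_map, window_top

__all__ = [
    "DecileBand",
    "PHLResult",
    "analysis_shell",
    "band_profile",
    "background_band",
    "detect_phl",
    "segment",
    "segment_phl",
]

logger = logging.getLogger(__name__)

#: 26-neighborhood connectivity structure
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: Allowed range of the adaptive threshold, in percent of SUVmax
THRESHOLD_PERCENT_RANGE = (20, 90)

#: Bands smaller than this are flagged unreliable (single-voxel noise guard)
MIN_BAND_VOXELS = 5

#: Stereological correction for voxel-face area counting: summing axis-aligned
#: faces overestimates the area of an isotropically oriented curved surface by
#: E[|nx|+|ny|+|nz|] = 3/2, so counted areas are scaled by 2/3.
FACE_AREA_CORRECTION = 2.0 / 3.0


@dataclass
class DecileBand:
    """One decile layer inside the analysis shell, with shell-thickness stats.

    Thickness is estimated as band volume divided by the mean of the inner
    and outer interface areas, the discrete analogue of shell thickness for
    a curved band.
    """

    k: int
    n_voxels: int
    volume_mm3: float
    inner_area_mm2: float
    outer_area_mm2: float
    thickness_mm: float
    reliable: bool = True

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n_voxels": self.n_voxels,
            "volume_mm3": self.volume_mm3,
            "inner_area_mm2": self.inner_area_mm2,
            "outer_area_mm2": self.outer_area_mm2,
            "thickness_mm": self.thickness_mm,
            "reliable": self.reliable,
        }


@dataclass
class PHLResult:
    """Outcome of halo detection: background band, halo band, threshold."""

    background_band: int
    phl_band: int
    threshold_percent: int
    threshold_suv: float
    detection_mode: str  # "abrupt_increase" | "fallback_adjacent"
    thickness_profile: list[DecileBand] = field(default_factory=list)
    clamped: bool = False

    def as_dict(self) -> dict:
        return {
            "background_band": self.background_band,
            "phl_band": self.phl_band,
            "threshold_percent": self.threshold_percent,
            "threshold_suv": self.threshold_suv,
            "detection_mode": self.detection_mode,
            "clamped": self.clamped,
            "thickness_profile": [b.as_dict() for b in self.thickness_profile],
        }


def _seed_component(supra: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    """26-connected component of a boolean field containing ``seed``."""
    labeled, _ = ndimage.label(supra, structure=STRUCT_26)
    lab = labeled[seed]
    if lab == 0:
        return np.zeros_like(supra, dtype=bool)
    return labeled == lab


def analysis_shell(volume: SUVVolume, roi: LesionROI, margin_mm: float = 15.0) -> np.ndarray:
    """Lesion-plus-rim region in which bands are analysed.

    The connected component containing the seed of ``{SUV >= 0.2 * top}`` is
    dilated by ``margin_mm`` (metric dilation via a Euclidean distance
    transform honouring anisotropic spacing) and clipped to the ROI box.
    """
    if margin_mm < 0:
        raise ParameterError(f"margin_mm must be >= 0, got {margin_mm}")
    top = window_top(roi.suvmax)
    supra = volume.values >= 0.2 * top
    comp = _seed_component(supra, roi.seed)
    if not comp.any():
        raise DetectionError("no FDG-avid component at the seed (seed below 20% of window top)")
    if margin_mm > 0:
        dist = ndimage.distance_transform_edt(~comp, sampling=volume.spacing)
        shell = dist <= margin_mm
    else:
        shell = comp
    clipped = np.zeros_like(shell)
    sl = roi.box_slices()
    clipped[sl] = shell[sl]
    if not clipped[roi.seed]:
        raise DetectionError("analysis shell does not contain the seed after ROI clipping")
    return clipped


def band_profile(
    labels: LayerLabelMap,
    shell: np.ndarray,
    spacing: tuple[float, float, float],
    min_voxels: int = MIN_BAND_VOXELS,
) -> list[DecileBand]:
    """Volume, interface areas and thickness of each decile band in the shell.

    Interface areas are estimated by counting voxel faces between the band
    and voxels of higher (inner) / lower (outer) label, scaled by the
    physical face area and by the 2/3 staircase correction for curved
    surfaces (axis-aligned face counting overestimates an isotropically
    oriented surface by 3/2). Bands with fewer than ``min_voxels`` voxels
    are flagged unreliable. Bands absent from the shell are omitted.
    """
    if not shell.any():
        raise DetectionError("empty analysis shell")
    lab = labels.labels
    voxvol = float(np.prod(spacing))
    # face area orthogonal to each axis
    face = [
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    ]
    bands: list[DecileBand] = []
    present = np.unique(lab[shell])
    for k in present.tolist():
        region = (lab == k) & shell
        n = int(region.sum())
        inner = 0.0
        outer = 0.0
        for ax in range(3):
            for shift in (-1, 1):
                nb = np.roll(lab, shift, axis=ax)
                # zero out wrap-around: faces at the grid edge do not count
                edge = [slice(None)] * 3
                edge[ax] = 0 if shift == 1 else -1
                valid = np.ones_like(region)
                valid[tuple(edge)] = False
                inner += face[ax] * np.count_nonzero(region & valid & (nb > k))
                outer += face[ax] * np.count_nonzero(region & valid & (nb < k))
        inner *= FACE_AREA_CORRECTION
        outer *= FACE_AREA_CORRECTION
        mean_area = 0.5 * (inner + outer)
        if mean_area > 0:
            thickness = n * voxvol / mean_area
        else:
            # isolated band with no interfaces: fall back to a cube-root scale
            thickness = (n * voxvol) ** (1.0 / 3.0)
        bands.append(
            DecileBand(
                k=int(k),
                n_voxels=n,
                volume_mm3=n * voxvol,
                inner_area_mm2=inner,
                outer_area_mm2=outer,
                thickness_mm=thickness,
                reliable=n >= min_voxels,
            )
        )
    return bands


def background_band(
    volume: SUVVolume,
    roi: LesionROI,
    labels: LayerLabelMap,
    margin_mm: float = 15.0,
    annulus_mm: float = 10.0,
) -> int:
    """Decile layer of the background activity around the lesion.

    The background is sampled on an annulus just outside the analysis shell
    (``margin_mm`` dilation of the avid component, then ``annulus_mm`` of
    further extent); the returned layer is the decile of the median SUV of
    that annulus.
    """
    top = labels.window.top
    supra = volume.values >= 0.2 * top
    comp = _seed_component(supra, roi.seed)
    if not comp.any():
        raise DetectionError("no FDG-avid component at the seed")
    # clip the core to the ROI box so a low-contrast lesion cannot swallow
    # the whole field of view
    core = np.zeros_like(comp)
    sl = roi.box_slices()
    core[sl] = comp[sl]
    dist = ndimage.distance_transform_edt(~core, sampling=volume.spacing)
    annulus = (dist > margin_mm) & (dist <= margin_mm + annulus_mm)
    if not annulus.any():
        raise DetectionError("background annulus is empty (lesion fills the volume)")
    med = float(np.median(volume.values[annulus]))
    b = int(np.floor(10 * med / top))
    return min(max(b, 0), 9)


def detect_phl(
    bands: list[DecileBand],
    b: int,
    rho: float = 2.0,
    top: float | None = None,
) -> PHLResult:
    """Pick the halo band and derive the adaptive tumor threshold.

    Candidate bands are ``k = b+1 .. 8`` (strictly between background and the
    hottest core). Scanning inward from the band adjacent to the background,
    a band belongs to the halo while it is at least ``rho`` times thicker
    than the next inner band; the halo's innermost such band ``k`` sets the
    threshold at ``10 * (k + 1)`` percent of SUVmax. If no band meets the
    criterion the band adjacent to the background is taken
    (``fallback_adjacent`` mode, the canonical halo geometry). The threshold
    is clamped to the observed 20-90% range with a warning.

    ``top`` (the display window top) converts the percent threshold into an
    absolute SUV; when omitted, ``threshold_suv`` is reported as NaN.
    """
    if not bands:
        raise DetectionError("no bands to analyse")
    if not 0 <= b <= 8:
        raise ParameterError(f"background band must be in 0..8, got {b}")
    if rho <= 1:
        raise ParameterError(f"abruptness ratio must exceed 1, got {rho}")
    by_k = {band.k: band for band in bands}
    candidates = [k for k in range(b + 1, 9) if k in by_k]
    if candidates and not any(by_k[k].reliable for k in candidates):
        raise DetectionError("all candidate bands are unreliable (too few voxels)")

    def thick(k: int) -> float | None:
        band = by_k.get(k)
        return band.thickness_mm if band is not None else None

    def abrupt(k: int) -> bool:
        band = by_k.get(k)
        if band is None or not band.reliable:
            return False
        inner = thick(k + 1)
        return inner is not None and inner > 0 and band.thickness_mm >= rho * inner

    k_phl = b + 1
    mode = "fallback_adjacent"
    if abrupt(b + 1):
        mode = "abrupt_increase"
        k = b + 1
        while k + 1 <= 8 and abrupt(k + 1):
            k += 1
        k_phl = k

    percent = 10 * (k_phl + 1)
    lo, hi = THRESHOLD_PERCENT_RANGE
    clamped = False
    if percent < lo or percent > hi:
        warnings.warn(
            f"PHL threshold {percent}% outside the {lo}-{hi}% range; clamping",
            stacklevel=2,
        )
        logger.warning("PHL threshold %d%% clamped to [%d, %d]", percent, lo, hi)
        percent = min(max(percent, lo), hi)
        clamped = True
    threshold_suv = float("nan") if top is None else percent / 100.0 * top
    return PHLResult(
        background_band=b,
        phl_band=k_phl,
        threshold_percent=percent,
        threshold_suv=threshold_suv,
        detection_mode=mode,
        thickness_profile=sorted(bands, key=lambda band: band.k),
        clamped=clamped,
    )


def segment(volume: SUVVolume, roi: LesionROI, threshold_suv: float, method: str = "") -> TumorMask:
    """Threshold the volume and keep the seed's 26-connected component.

    Returns an empty mask (not an error) when the seed itself lies below the
    threshold.
    """
    if threshold_suv <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold_suv}")
    supra = volume.values >= threshold_suv
    comp = _seed_component(supra, roi.seed)
    return TumorMask(
        mask=comp,
        spacing=volume.spacing,
        threshold_suv=threshold_suv,
        seed=roi.seed,
        method=method,
    )


def segment_phl(
    volume: SUVVolume,
    roi: LesionROI,
    margin_mm: float = 15.0,
    rho: float = 2.0,
    min_voxels: int = MIN_BAND_VOXELS,
) -> tuple[PHLResult, TumorMask, LayerLabelMap]:
    """Full adaptive pipeline: deciles, shell, bands, halo, segmentation."""
    labels = decile_label_map(volume, roi)
    shell = analysis_shell(volume, roi, margin_mm=margin_mm)
    bands = band_profile(labels, shell, volume.spacing, min_voxels=min_voxels)
    b = background_band(volume, roi, labels, margin_mm=margin_mm)
    result = detect_phl(bands, b, rho=rho, top=labels.window.top)
    mask = segment(volume, roi, result.threshold_suv, method="phl")
    mask.threshold_percent = result.threshold_percent
    logger.info(
        "PHL detection: background band %d, halo band %d, threshold %d%% (%.3f SUV), mode=%s",
        result.background_band,
        result.phl_band,
        result.threshold_percent,
        result.threshold_suv,
        result.detection_mode,
    )
    return result, mask, labels
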