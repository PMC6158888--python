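"""Lesion metrics: metabolic tumor length, volume, SUVmean, TLG, pattern.

Metabolic tumor length (ML) is the craniocaudal (z) extent of the mask,
mirroring a straight sagittal ruler measurement along the esophagus; extents
count inclusive voxel spans, so a single-voxel mask has the length of one
voxel. Lengths are reported in cm, volumes in mL. TLG is SUVmean times MTV.

The visual homogeneous/heterogeneous classification is proxied
quantitatively: a lesion is heterogeneous when it has two or more distinct
>90% hot cores, or a single core whose centroid is eccentric within the mask
(offset beyond a configurable fraction of the mask's equivalent-sphere
radius). The 0.35 offset cutoff is a proxy constant of this package, not a
published value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import HalopetError, SUVVolume, TumorMask
from .deciles import LayerLabelMap
from .phl import STRUCT_26

__all__ = [
    "LesionMetrics",
    "metabolic_length",
    "metabolic_volume",
    "lesion_metrics",
    "classify_pattern",
]

#: single-core eccentricity cutoff, as a fraction of the equivalent-sphere radius
ECCENTRICITY_CUTOFF = 0.35


@dataclass
class LesionMetrics:
    ml_cm: float
    mtv_ml: float
    suv_mean: float
    tlg: float
    pattern: str  # "homogeneous" | "heterogeneous" | "undefined"
    n_cores: int

    def as_dict(self) -> dict:
        return {
            "ml_cm": self.ml_cm,
            "mtv_ml": self.mtv_ml,
            "suv_mean": self.suv_mean,
            "tlg": self.tlg,
            "pattern": self.pattern,
            "n_cores": self.n_cores,
        }


def metabolic_length(mask: TumorMask, axis: str = "craniocaudal") -> float:
    """Metabolic tumor length in cm.

    ``axis='craniocaudal'`` (default) measures the inclusive z-index span
    times the z spacing. ``axis='principal'`` instead measures the extent
    along the mask's first principal axis plus one mean voxel, for lesions
    that are markedly oblique to the scanner axis.
    """
    if mask.empty:
        return 0.0
    if axis == "craniocaudal":
        zs = np.nonzero(mask.mask.any(axis=(0, 1)))[0]
        extent_mm = (zs.max() - zs.min() + 1) * mask.spacing[2]
    elif axis == "principal":
        coords = np.argwhere(mask.mask) * np.asarray(mask.spacing)
        centered = coords - coords.mean(axis=0)
        if len(coords) == 1:
            extent_mm = float(np.mean(mask.spacing))
        else:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            proj = centered @ vt[0]
            extent_mm = float(proj.max() - proj.min()) + float(np.mean(mask.spacing))
    else:
        raise ValueError(f"unknown axis mode {axis!r}")
    return float(extent_mm) / 10.0


def metabolic_volume(mask: TumorMask) -> float:
    """Metabolic tumor volume in mL (voxel count times voxel volume)."""
    voxvol_mm3 = float(np.prod(mask.spacing))
    return mask.n_voxels * voxvol_mm3 / 1000.0


def classify_pattern(labels: LayerLabelMap, mask: TumorMask) -> tuple[str, int]:
    """Homogeneous vs heterogeneous uptake pattern, with hot-core count.

    Cores are 26-connected components of label-9 (>90% of SUVmax) voxels
    within the mask. Multiple cores, or a single markedly eccentric core,
    classify the lesion as heterogeneous.
    """
    if mask.empty:
        raise HalopetError("cannot classify an empty mask")
    hot = (labels.labels == 9) & mask.mask
    if not hot.any():
        raise HalopetError("no >90% core inside the mask: inconsistent label map and mask")
    _, n_cores = ndimage.label(hot, structure=STRUCT_26)
    if n_cores >= 2:
        return "heterogeneous", int(n_cores)
    spacing = np.asarray(mask.spacing)
    core_centroid = np.argwhere(hot).mean(axis=0) * spacing
    mask_centroid = np.argwhere(mask.mask).mean(axis=0) * spacing
    offset = float(np.linalg.norm(core_centroid - mask_centroid))
    volume_mm3 = mask.n_voxels * float(np.prod(spacing))
    r_eq = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    pattern = "heterogeneous" if offset > ECCENTRICITY_CUTOFF * r_eq else "homogeneous"
    return pattern, 1


def lesion_metrics(
    volume: SUVVolume,
    mask: TumorMask,
    labels: LayerLabelMap | None = None,
) -> LesionMetrics:
    """All per-lesion metrics for one segmentation.

    An empty mask yields zeroed metrics with an undefined pattern. Pattern
    classification requires the decile label map; omit it to skip pattern
    assignment.
    """
    if mask.empty:
        return LesionMetrics(0.0, 0.0, 0.0, 0.0, "undefined", 0)
    suv_mean = float(volume.values[mask.mask].mean())
    mtv = metabolic_volume(mask)
    ml = metabolic_length(mask)
    tlg = suv_mean * mtv
    if labels is not None:
        pattern, n_cores = classify_pattern(labels, mask)
    else:
        pattern, n_cores = "undefined", 0
    return LesionMetrics(ml_cm=ml, mtv_ml=mtv, suv_mean=suv_mean, tlg=tlg, pattern=pattern, n_cores=n_cores)
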