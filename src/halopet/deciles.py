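"""Decile quantization of lesion SUV: the digital "10-step color scale".

The halo-layer workflow displays the lesion with the PET window bottom fixed
at SUV 0 and the top set slightly above the lesion SUVmax (rounded up to the
next 0.1), then quantizes the display into ten equal layers. Layer ``k``
covers SUV in ``[k/10, (k+1)/10) * top``, so each layer spans 10% of SUVmax
up to the <0.1 rounding of the window top. The hottest voxel always falls in
layer 9 (the >90% core) because the top strictly exceeds SUVmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LesionROI, ParameterError, SUVVolume

__all__ = ["WindowSettings", "LayerLabelMap", "window_top", "decile_label_map"]

N_LAYERS = 10


def window_top(suvmax: float) -> float:
    """Window upper bound: the smallest multiple of 0.1 strictly above SUVmax.

    E.g. any SUVmax in 13.00-13.09 maps to a top of 13.1. A small epsilon
    guards against binary-float representations of exact multiples of 0.1.
    """
    if suvmax <= 0:
        raise ParameterError(f"suvmax must be positive, got {suvmax}")
    return (math.floor(suvmax * 10 + 1e-9) + 1) / 10


@dataclass(frozen=True)
class WindowSettings:
    """PET display window for halo identification: [0, top] in ten layers."""

    top: float
    bottom: float = 0.0
    n_layers: int = N_LAYERS


@dataclass
class LayerLabelMap:
    """Integer field assigning each voxel its SUVmax-decile layer (0-9)."""

    labels: np.ndarray
    window: WindowSettings
    source_suvmax: float


def decile_label_map(volume: SUVVolume, roi: LesionROI) -> LayerLabelMap:
    """Quantize a volume into the ten SUVmax-decile layers of ``roi``.

    Per-voxel label = clamp(floor(10 * SUV / top), 0, 9); labels are monotone
    non-decreasing in SUV, and exactly the voxels with SUV >= 0.9 * top carry
    label 9. Voxels hotter than the window top (possible outside the lesion,
    e.g. myocardium) clamp to 9; halo detection is restricted to the lesion
    shell so they cannot corrupt it.
    """
    top = window_top(roi.suvmax)
    labels = np.floor(N_LAYERS * volume.values / top).astype(np.int8)
    np.clip(labels, 0, N_LAYERS - 1, out=labels)
    return LayerLabelMap(labels=labels, window=WindowSettings(top=top), source_suvmax=roi.suvmax)
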