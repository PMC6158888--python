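"""Fixed-threshold comparator segmentations.

Two workstation-standard methods the adaptive halo threshold is compared
against: a fixed absolute cutoff at SUV 2.5 and a fixed percentage of SUVmax
(40% by default). Percentage thresholds reference the display window top
(which exceeds SUVmax by < 0.1), consistent with the decile quantization; the
relative deviation from a true %SUVmax threshold is below 0.1 / SUVmax.
"""

from __future__ import annotations

from .core import LesionROI, ParameterError, SUVVolume, TumorMask
from .deciles import window_top
from .phl import segment

__all__ = ["segment_fixed_suv", "segment_percent"]


def segment_fixed_suv(volume: SUVVolume, roi: LesionROI, suv_cut: float = 2.5) -> TumorMask:
    """Segment at a fixed absolute SUV cutoff (default 2.5).

    When the lesion SUVmax is below the cutoff the mask is empty and the
    downstream metabolic length is recorded as 0.
    """
    if suv_cut <= 0:
        raise ParameterError(f"suv_cut must be positive, got {suv_cut}")
    return segment(volume, roi, suv_cut, method=f"suv{suv_cut:g}")


def segment_percent(volume: SUVVolume, roi: LesionROI, pct: float = 40.0) -> TumorMask:
    """Segment at a fixed percentage of SUVmax (default 40%)."""
    if not 0 < pct < 100:
        raise ParameterError(f"pct must be in (0, 100), got {pct}")
    threshold = pct / 100.0 * window_top(roi.suvmax)
    mask = segment(volume, roi, threshold, method=f"pct{pct:g}")
    mask.threshold_percent = pct
    return mask
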