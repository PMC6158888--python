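"""Orchestration: run segmentation methods per lesion and evaluate cohorts.

``run_methods`` applies any subset of {adaptive halo, fixed SUV 2.5, fixed
%SUVmax} to one lesion and emits one metrics row per method.
``evaluate_cohort`` reproduces the validation design on a table of per-lesion
lengths: per-method regression against the reference length, Bland-Altman
agreement, Spearman correlation of the signed error with SUVmax, and a
Kruskal-Wallis/Dunn comparison of absolute errors across methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LesionROI, SUVVolume, TumorMask
from .deciles import decile_label_map
from .fixed import segment_fixed_suv, segment_percent
from .metrics import lesion_metrics
from .phl import PHLResult, segment_phl
from .stats import (
    absolute_difference_comparison,
    bland_altman,
    linear_regression,
    spearman,
)

__all__ = ["run_methods", "evaluate_cohort", "METHODS"]

METHODS = ("phl", "suv2.5", "pct40")


def run_methods(
    volume: SUVVolume,
    roi: LesionROI,
    methods: tuple[str, ...] = METHODS,
    rho: float = 2.0,
    margin_mm: float = 15.0,
    lesion_id: str = "lesion",
) -> tuple[list[dict], PHLResult | None, dict[str, TumorMask]]:
    """Apply the requested methods to one lesion.

    Returns (metrics rows, halo detection result if run, masks by method).
    ``pct:<k>`` selects a fixed percentage other than 40.
    """
    labels = decile_label_map(volume, roi)
    rows: list[dict] = []
    masks: dict[str, TumorMask] = {}
    phl_result: PHLResult | None = None
    for method in methods:
        if method == "phl":
            phl_result, mask, labels = segment_phl(volume, roi, margin_mm=margin_mm, rho=rho)
        elif method == "suv2.5":
            mask = segment_fixed_suv(volume, roi, 2.5)
        elif method == "pct40":
            mask = segment_percent(volume, roi, 40.0)
        elif method.startswith("pct:"):
            mask = segment_percent(volume, roi, float(method.split(":", 1)[1]))
        else:
            raise ValueError(f"unknown method {method!r}")
        m = lesion_metrics(volume, mask, labels if not mask.empty else None)
        rows.append(
            {
                "lesion_id": lesion_id,
                "method": method,
                "threshold_percent": mask.threshold_percent,
                "threshold_suv": mask.threshold_suv,
                "suvmax": roi.suvmax,
                **m.as_dict(),
            }
        )
        masks[method] = mask
    return rows, phl_result, masks


def evaluate_cohort(table: pd.DataFrame) -> dict:
    """Validation statistics for a cohort metrics table.

    ``table`` needs columns ``lesion_id``, ``method``, ``ml_cm``,
    ``truth_cm`` and ``suvmax``. Per method: OLS regression of measured vs
    reference length, Bland-Altman agreement, and the Spearman correlation
    of the signed length error with SUVmax. Across methods: Kruskal-Wallis
    with Dunn post-hoc on the absolute errors. Regression and correlation
    are skipped (with a note) below 3 lesions.
    """
    required = {"lesion_id", "method", "ml_cm", "truth_cm", "suvmax"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    report: dict = {"per_method": {}, "absolute_error_comparison": None}
    abs_errors: dict[str, np.ndarray] = {}
    for method, sub in table.groupby("method", sort=False):
        ml = sub["ml_cm"].to_numpy(float)
        truth = sub["truth_cm"].to_numpy(float)
        suvmax = sub["suvmax"].to_numpy(float)
        entry: dict = {"n": int(len(sub))}
        if len(sub) >= 3 and np.ptp(truth) > 0:
            entry["regression"] = linear_regression(truth, ml).as_dict()
            entry["bland_altman"] = bland_altman(ml, truth).as_dict()
            rho_s, p_s = spearman(suvmax, ml - truth)
            entry["error_vs_suvmax_spearman"] = {"rho": rho_s, "p": p_s}
        else:
            entry["note"] = "fewer than 3 lesions or constant reference; statistics skipped"
        report["per_method"][method] = entry
        abs_errors[method] = np.abs(ml - truth)
    if len(abs_errors) >= 2 and all(len(v) >= 3 for v in abs_errors.values()):
        report["absolute_error_comparison"] = absolute_difference_comparison(abs_errors).as_dict()
    return report
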