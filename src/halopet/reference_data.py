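"""Reference worked-example data for the agreement statistics.

``INTEROBSERVER_THRESHOLD_TABLE`` is the published 8x8 cross-tabulation of
adaptive halo tumor thresholds assigned independently by two nuclear
medicine readers to 85 FDG-avid esophageal carcinomas (rows: observer B,
columns: observer A, ordinal levels 20%..90% of SUVmax). Its linearly
weighted kappa of 0.936 is the canonical "very good agreement" worked
example for :func:`halopet.stats.weighted_kappa`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["THRESHOLD_LEVELS", "INTEROBSERVER_THRESHOLD_TABLE"]

#: ordinal threshold levels, percent of SUVmax
THRESHOLD_LEVELS = (20, 30, 40, 50, 60, 70, 80, 90)

#: rows = observer B, columns = observer A; total n = 85
INTEROBSERVER_THRESHOLD_TABLE = np.array(
    [
        [2, 0, 0, 0, 0, 0, 0, 0],
        [1, 40, 0, 0, 0, 0, 0, 0],
        [0, 2, 13, 0, 0, 0, 0, 0],
        [0, 0, 2, 6, 0, 0, 0, 0],
        [0, 0, 0, 1, 2, 2, 0, 0],
        [0, 0, 0, 0, 0, 5, 1, 0],
        [0, 0, 0, 0, 0, 1, 5, 0],
        [0, 0, 0, 0, 0, 0, 0, 2],
    ],
    dtype=int,
)
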