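"""Agreement and validation statistics.

The validation toolkit used to compare metabolic lengths against a reference
standard: ordinary least-squares regression, Bland-Altman agreement with a
proportional-error test, Spearman rank correlation, weighted Cohen's kappa
for ordinal inter-observer tables, and a Kruskal-Wallis comparison of
absolute errors with Dunn's pairwise post-hoc test.

Regression, rank correlation and Kruskal-Wallis delegate to scipy; the
weighted kappa and Dunn post-hoc are computed here from their standard
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import InputError, ParameterError

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "KappaResult",
    "GroupComparisonResult",
    "linear_regression",
    "bland_altman",
    "spearman",
    "weighted_kappa",
    "absolute_difference_comparison",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    prop_r: float
    prop_p: float
    prop_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "prop_r": self.prop_r,
            "prop_p": self.prop_p,
            "prop_defined": self.prop_defined,
        }


@dataclass
class KappaResult:
    kappa: float
    weights: str
    table: np.ndarray

    def as_dict(self) -> dict:
        return {"kappa": self.kappa, "weights": self.weights, "table": self.table.tolist()}


@dataclass
class GroupComparisonResult:
    medians: dict[str, float]
    iqr: dict[str, tuple[float, float]]
    h_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], dict]

    def as_dict(self) -> dict:
        return {
            "medians": self.medians,
            "iqr": {k: list(v) for k, v in self.iqr.items()},
            "h_statistic": self.h_statistic,
            "p_value": self.p_value,
            "pairwise": {f"{a}|{b}": d for (a, b), d in self.pairwise.items()},
        }


def _check_paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"expected equal-length 1-D sequences, got {x.shape} and {y.shape}")
    if len(x) < min_n:
        raise InputError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; R^2 is the squared Pearson r."""
    x, y = _check_paired(x, y)
    if np.ptp(x) == 0:
        raise InputError("x is constant; regression is degenerate")
    if np.ptp(y) == 0:
        # a flat response: zero slope and no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of measurements ``a`` against reference ``b``.

    Differences are ``a - b``; bias is their mean, SD the sample (n-1)
    standard deviation, and the limits of agreement bias +/- 1.96 SD.
    Proportional error is the Pearson correlation of the differences with
    the pairwise means; it is flagged undefined when either is constant.
    """
    a, b = _check_paired(a, b)
    d = a - b
    mean_ab = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if np.ptp(mean_ab) == 0 or np.ptp(d) == 0:
        return BlandAltmanResult(bias, sd, loa_low, loa_high, float("nan"), float("nan"), False)
    import warnings

    with warnings.catch_warnings():
        # float-rounding can leave the differences "near constant"; the test
        # is then numerically meaningless and flagged undefined below
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        warnings.simplefilter("ignore", sps.NearConstantInputWarning)
        r, p = sps.pearsonr(d, mean_ab)
    if not np.isfinite(r):
        return BlandAltmanResult(bias, sd, loa_low, loa_high, float("nan"), float("nan"), False)
    return BlandAltmanResult(bias, sd, loa_low, loa_high, float(r), float(p), True)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p."""
    x, y = _check_paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def weighted_kappa(table, weights: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa on a square ordinal contingency table.

    kappa = 1 - sum(w * O) / sum(w * E), with disagreement weights
    ``w_ij = |i - j| / (m - 1)`` (linear) or its square (quadratic),
    O the observed proportions, and E the outer product of the marginals.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise InputError(f"contingency table must be square, got shape {T.shape}")
    if T.shape[0] < 2:
        raise InputError("need at least 2 ordinal categories")
    if np.any(T < 0) or T.sum() < 1:
        raise InputError("table entries must be non-negative with positive total")
    if weights not in ("linear", "quadratic"):
        raise ParameterError(f"weights must be 'linear' or 'quadratic', got {weights!r}")
    m = T.shape[0]
    P = T / T.sum()
    E = np.outer(P.sum(axis=1), P.sum(axis=0))
    idx = np.arange(m)
    w = np.abs(idx[:, None] - idx[None, :]) / (m - 1)
    if weights == "quadratic":
        w = w**2
    kappa = 1.0 - float((w * P).sum() / (w * E).sum())
    return KappaResult(kappa=kappa, weights=weights, table=np.asarray(table))


def _dunn_posthoc(
    groups: dict[str, np.ndarray], alpha: float, bonferroni: bool
) -> dict[tuple[str, str], dict]:
    """Dunn's rank-sum pairwise z tests with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], dict] = {}
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            if bonferroni:
                p = min(1.0, p * n_pairs)
            out[(g1, g2)] = {"z": float(z), "p": float(p), "significant": bool(p < alpha)}
    return out


def absolute_difference_comparison(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> GroupComparisonResult:
    """Compare groups of absolute errors |ML - reference| across methods.

    Per-group medians and interquartile ranges, a tie-corrected
    Kruskal-Wallis H test, and Dunn's pairwise post-hoc z tests at ``alpha``
    (uncorrected by default; set ``bonferroni=True`` to adjust).
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 3:
            raise InputError(f"group {name!r} has fewer than 3 values")
        arrays[name] = arr
    medians = {g: float(np.median(a)) for g, a in arrays.items()}
    iqr = {
        g: (float(np.percentile(a, 25)), float(np.percentile(a, 75))) for g, a in arrays.items()
    }
    h, p = sps.kruskal(*arrays.values())
    pairwise = _dunn_posthoc(arrays, alpha=alpha, bonferroni=bonferroni)
    return GroupComparisonResult(
        medians=medians, iqr=iqr, h_statistic=float(h), p_value=float(p), pairwise=pairwise
    )
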