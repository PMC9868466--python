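"""Interlaboratory agreement: Passing-Bablok regression, Bland-Altman
analysis, and concentration-binned range-based bias.

Passing-Bablok regression follows the original shifted-median procedure:
the slope is the median of all pairwise slopes, offset by the number of
slopes below -1; rank-based confidence intervals come from the normal
approximation to Kendall's tau.  Constant bias means the intercept CI
excludes 0; proportional bias means the slope CI excludes 1.

Bland-Altman differences are lab A minus lab B (A is the minuend), either
absolute (ng/mL) or as a percentage of the pair mean; limits of agreement
are mean +/- 1.96 SD with t-based confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import PairedComparison
from .precision import AnalysisError

__all__ = [
    "PassingBablokFit",
    "BlandAltmanResult",
    "ConcentrationBin",
    "passing_bablok",
    "bland_altman",
    "bin_by_concentration",
    "loa_width",
]


@dataclass
class PassingBablokFit:
    slope: float
    slope_ci: tuple[float, float] | None
    intercept: float
    intercept_ci: tuple[float, float] | None
    n_pairs_used: int
    n_slopes_excluded: int
    alpha: float
    constant_bias_present: bool | None
    proportional_bias_present: bool | None
    meta: dict = field(default_factory=dict)


def _offset_median(sorted_vals: np.ndarray, offset: int) -> float:
    """Median of a sorted array, shifted ``offset`` ranks upward."""
    n = sorted_vals.size
    if n % 2 == 1:
        idx = (n - 1) // 2 + offset
        if not 0 <= idx < n:
            raise AnalysisError("offset median rank out of range; need more pairs")
        return float(sorted_vals[idx])
    i1 = n // 2 - 1 + offset
    i2 = n // 2 + offset
    if not (0 <= i1 < n and 0 <= i2 < n):
        raise AnalysisError("offset median rank out of range; need more pairs")
    return float((sorted_vals[i1] + sorted_vals[i2]) / 2.0)


def passing_bablok(
    pairs: PairedComparison, alpha: float = 0.05, require_ci: bool = True
) -> PassingBablokFit:
    """Passing-Bablok regression of lab B (y) on lab A (x).

    All pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i), i < j, are formed;
    slopes with x_i = x_j (undefined) or exactly -1 are excluded.  With K
    the count of slopes below -1, the slope estimate is the K-offset median
    of the sorted slopes; its CI bounds are the order statistics at ranks
    M1 = round((N - w)/2) (half up) and M2 = N - M1 + 1, both shifted by K,
    with w = z_{1-alpha/2} * sqrt(n(n-1)(2n+5)/18).  The intercept is
    median(y - slope*x); its CI endpoints use the slope CI bounds.

    At very small n the CI ranks fall outside 1..N; that raises unless
    ``require_ci=False``, in which case the point estimates are returned
    with CIs and bias flags set to None.
    """
    x, y = pairs.a, pairs.b
    n = x.size
    if n < 3:
        raise AnalysisError("Passing-Bablok needs n >= 3 pairs")
    if np.ptp(x) == 0:
        raise AnalysisError("all x values equal; slope undefined")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    defined = dx != 0
    slopes = dy[defined] / dx[defined]
    keep = slopes != -1.0
    slopes = np.sort(slopes[keep])
    n_excluded = int((~defined).sum() + (~keep).sum())
    N = slopes.size
    if N == 0:
        raise AnalysisError("all pairwise slopes excluded")

    K = int((slopes < -1.0).sum())
    slope = _offset_median(slopes, K)

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = math.floor((N - w) / 2.0 + 0.5)  # round half up
    m2 = N - m1 + 1
    lo_rank, hi_rank = m1 + K, m2 + K
    intercept = float(np.median(y - slope * x))
    meta = {"direction": f"{pairs.label_b} (y) on {pairs.label_a} (x)"}
    if lo_rank < 1 or hi_rank > N:
        if require_ci:
            raise AnalysisError(
                f"confidence ranks ({lo_rank}, {hi_rank}) outside 1..{N}; "
                "too few pairs for a Passing-Bablok CI at this alpha"
            )
        return PassingBablokFit(
            slope=slope, slope_ci=None, intercept=intercept, intercept_ci=None,
            n_pairs_used=n, n_slopes_excluded=n_excluded, alpha=alpha,
            constant_bias_present=None, proportional_bias_present=None, meta=meta,
        )
    slope_lo = float(slopes[lo_rank - 1])
    slope_hi = float(slopes[hi_rank - 1])

    e1 = float(np.median(y - slope_hi * x))
    e2 = float(np.median(y - slope_lo * x))
    int_lo, int_hi = min(e1, e2), max(e1, e2)

    return PassingBablokFit(
        slope=slope,
        slope_ci=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci=(int_lo, int_hi),
        n_pairs_used=n,
        n_slopes_excluded=n_excluded,
        alpha=alpha,
        constant_bias_present=not (int_lo <= 0.0 <= int_hi),
        proportional_bias_present=not (slope_lo <= 1.0 <= slope_hi),
        meta=meta,
    )


@dataclass
class BlandAltmanResult:
    mode: str  # "absolute" or "percent"
    n: int
    mean_bias: float
    mean_bias_ci: tuple[float, float]
    sd_diff: float
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    loa_interval_width: float
    proportional_error_slope: float
    proportional_error_p: float
    meta: dict = field(default_factory=dict)


def loa_width(loa_lower: float, loa_upper: float) -> float:
    """Width of the limits-of-agreement interval (upper minus lower)."""
    return loa_upper - loa_lower


def bland_altman(pairs: PairedComparison, mode: str = "percent") -> BlandAltmanResult:
    """Bland-Altman agreement of lab A against lab B (difference = A - B).

    ``mode='absolute'`` uses d = a - b in ng/mL; ``mode='percent'`` uses
    100 * (a - b) / pair mean.  LoA = mean +/- 1.96 SD; the mean-bias CI is
    mean +/- t * SD/sqrt(n) and each LoA CI is LoA +/- t * SD * sqrt(3/n)
    (t at 0.975, n-1 df).  The proportional-error slope is the OLS slope
    of d against the pair means.
    """
    if mode not in ("absolute", "percent"):
        raise AnalysisError(f"unknown Bland-Altman mode {mode!r}")
    a, b = pairs.a, pairs.b
    n = a.size
    if n < 3:
        raise AnalysisError("Bland-Altman needs n >= 3 pairs")
    means = (a + b) / 2.0
    if mode == "percent":
        zero = np.flatnonzero(means == 0)
        if zero.size:
            sid = pairs.data["sample_id"].iloc[int(zero[0])]
            raise AnalysisError(f"pair mean is zero for sample {sid!r}; percent mode undefined")
        d = 100.0 * (a - b) / means
    else:
        d = a - b

    mean_bias = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    loa_lo = mean_bias - 1.96 * sd
    loa_hi = mean_bias + 1.96 * sd
    half_mean = t * sd / math.sqrt(n)
    half_loa = t * sd * math.sqrt(3.0 / n)

    if sd == 0 or np.ptp(means) == 0:
        pe_slope, pe_p = 0.0, 1.0
    else:
        reg = stats.linregress(means, d)
        pe_slope, pe_p = float(reg.slope), float(reg.pvalue)
        if math.isnan(pe_p):
            pe_p = 1.0

    return BlandAltmanResult(
        mode=mode,
        n=n,
        mean_bias=mean_bias,
        mean_bias_ci=(mean_bias - half_mean, mean_bias + half_mean),
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_lower_ci=(loa_lo - half_loa, loa_lo + half_loa),
        loa_upper=loa_hi,
        loa_upper_ci=(loa_hi - half_loa, loa_hi + half_loa),
        loa_interval_width=loa_width(loa_lo, loa_hi),
        proportional_error_slope=pe_slope,
        proportional_error_p=pe_p,
        meta={"minuend": pairs.label_a, "subtrahend": pairs.label_b},
    )


@dataclass
class ConcentrationBin:
    bin_id: str
    sample_ids: list[str]
    range: tuple[float, float]  # min, max of member pair means (ng/mL)
    bin_bias_pct: float  # mean per-pair percentage difference (A - B)


def bin_by_concentration(pairs: PairedComparison, n_bins: int = 5) -> list[ConcentrationBin]:
    """Partition samples into contiguous concentration bins of near-equal size.

    Samples are sorted by pair mean (ties broken by sample_id) and split
    into ``n_bins`` contiguous groups, the larger groups first when the
    count does not divide evenly.  Each bin carries the mean of its
    members' percentage differences (range-based bias).
    """
    n = len(pairs)
    if n_bins < 1:
        raise AnalysisError("n_bins must be >= 1")
    if n_bins > n:
        raise AnalysisError(f"n_bins={n_bins} exceeds the {n} samples available")
    a, b = pairs.a, pairs.b
    means = (a + b) / 2.0
    if (means == 0).any():
        raise AnalysisError("zero pair mean; percentage difference undefined")
    pct = 100.0 * (a - b) / means
    sids = pairs.data["sample_id"].to_numpy()
    order = np.lexsort((sids, means))

    q, r = divmod(n, n_bins)
    sizes = [q + 1] * r + [q] * (n_bins - r)
    bins: list[ConcentrationBin] = []
    start = 0
    for k, size in enumerate(sizes, start=1):
        idx = order[start : start + size]
        start += size
        bins.append(
            ConcentrationBin(
                bin_id=f"G{k}",
                sample_ids=[str(s) for s in sids[idx]],
                range=(float(means[idx].min()), float(means[idx].max())),
                bin_bias_pct=float(pct[idx].mean()),
            )
        )
    return bins
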