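"""Paired statistics for the reporting layer.

Two procedures: the Wilcoxon signed-rank test for pre/post-treatment
comparison of flow quantities, and the intra-class correlation
coefficient for agreement between intra-stent and stent-free velocity
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, ParameterError

EXACT_N_MAX = 20  # exact signed-rank distribution up to this many pairs


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_effective: int  # pairs after dropping zero differences
    method: str  # "exact" or "normal"
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments, mid-rank ties allowed.

    The null distribution of W+ is the distribution of a random subset
    sum of the ranks; doubling the (possibly half-integer) mid-ranks
    makes them integers, so the distribution is the coefficient vector
    of prod(1 + x^(2 r_i)) — computed by repeated convolution.  The
    distribution is symmetric about S/2 (global sign flip), and the
    two-sided p is P(W+ <= w_lo) + P(W+ >= S - w_lo) with
    w_lo = min(w, S - w).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    w_lo = min(w2, total - w2)
    p = dist[:w_lo + 1].sum() + dist[total - w_lo:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(pre, post) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties get mid-ranks.  The p-value is
    exact (full sign-assignment distribution, ties handled) for up to
    20 effective pairs and a tie-corrected normal approximation with
    continuity correction beyond.  All differences zero is degenerate
    and reported as p = 1 with a flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise DataError("pre and post must be equal-length 1-D samples")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    # normal approximation with tie correction and continuity correction
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal")


@dataclass
class ICCResult:
    icc: float
    model: str
    n: int
    degenerate: bool = False


def icc_agreement(x, y, model: str = "ICC(A,1)") -> ICCResult:
    """Intra-class correlation between two paired measurement conditions.

    Default model is the two-way mixed-effects, absolute-agreement,
    single-measurement ICC(A,1) (McGraw & Wong): with n subjects and
    k = 2 conditions,

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the rows (subjects), columns (conditions)
    and error mean squares of the two-way ANOVA.  Absolute agreement
    penalizes a constant offset between conditions, which consistency
    (``model="ICC(C,1)"``) does not.  Zero variance in both conditions
    is degenerate (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 3:
        raise DataError("ICC needs at least 3 paired measurements")
    if model not in ("ICC(A,1)", "ICC(C,1)"):
        raise ParameterError(f"unsupported ICC model {model!r}")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr == 0 and msc == 0 and mse == 0:
        return ICCResult(float("nan"), model, n, degenerate=True)
    if model == "ICC(A,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        return ICCResult(float("nan"), model, n, degenerate=True)
    return ICCResult(float((msr - mse) / denom), model, n)
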