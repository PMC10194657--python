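"""Agreement statistics between the wearable and reference pipelines.

Matched walking bouts yield per-bout errors E_j = DMO_test,j − DMO_ref,j and
relative errors E%_j = 100·E_j/DMO_ref,j, summarized by mean/median (signed
and absolute) and interquartile range. Normality is checked with
Shapiro–Wilk. Absolute agreement is quantified by the single-measure
two-way random-effects intraclass correlation ICC(2,1) with an F-based 95%
confidence interval, classed as poor (<0.5), moderate (0.5–0.75), good
(0.75–0.9) or excellent (>0.9). A Bonett-type closed form plans the number
of bouts needed for a target ICC confidence-interval width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class MatchedBoutPair:
    """One walking bout detected by both systems."""

    test: object  # WalkingBout-like (t_start, t_end, dmo)
    ref: object
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in (0, 1]")


@dataclass
class ErrorSummary:
    me: float  # mean error (bias)
    mae: float  # mean absolute error
    mde: float  # median error
    mdae: float  # median absolute error
    iqre: float  # interquartile range of errors
    me_pct: float
    mae_pct: float
    mde_pct: float
    mdae_pct: float
    iqre_pct: float
    n: int


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    icc_class: str  # poor | moderate | good | excellent


# ---------------------------------------------------------------------------


def match_bouts(
    test_bouts: Sequence, ref_bouts: Sequence, min_overlap: float = 0.5
) -> list[MatchedBoutPair]:
    """One-to-one greedy matching of bouts by temporal overlap.

    The overlap fraction is the intersection divided by the shorter span;
    pairs below ``min_overlap`` are not matched.
    """
    cands = []
    for i, tb in enumerate(test_bouts):
        for j, rb in enumerate(ref_bouts):
            inter = min(tb.t_end, rb.t_end) - max(tb.t_start, rb.t_start)
            shorter = min(tb.t_end - tb.t_start, rb.t_end - rb.t_start)
            if inter <= 0 or shorter <= 0:
                continue
            frac = inter / shorter
            if frac >= min_overlap:
                cands.append((frac, inter, i, j))
    # best fraction first; equal fractions resolved by absolute overlap
    cands.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used_t: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for frac, _, i, j in cands:
        if i in used_t or j in used_r:
            continue
        used_t.add(i)
        used_r.add(j)
        pairs.append(
            MatchedBoutPair(test=test_bouts[i], ref=ref_bouts[j], overlap_fraction=min(frac, 1.0))
        )
    pairs.sort(key=lambda p: p.test.t_start)
    return pairs


def compute_errors(
    pairs: Sequence[MatchedBoutPair], dmo_name: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bout errors E_j = test − ref and relative errors E%_j (in %).

    Pairs with a zero reference value are excluded from the relative series
    with a warning (E%_j undefined there).
    """
    e = []
    e_pct = []
    for p in pairs:
        tv = float(p.test.dmo.as_dict()[dmo_name])
        rv = float(p.ref.dmo.as_dict()[dmo_name])
        err = tv - rv
        e.append(err)
        if rv == 0.0:
            warnings.warn(f"reference {dmo_name} is zero; relative error undefined, excluded")
        else:
            e_pct.append(err / rv * 100.0)
    return np.asarray(e, dtype=float), np.asarray(e_pct, dtype=float)


def summarize_errors(e: np.ndarray, e_pct: Optional[np.ndarray] = None) -> ErrorSummary:
    """Bias/accuracy/precision summary: mean, mean-absolute, median,
    median-absolute and IQR of the error series (type-7 quartiles)."""
    e = np.asarray(e, dtype=float)
    if len(e) == 0:
        raise ValueError("cannot summarize an empty error series")
    if e_pct is None:
        e_pct = np.array([])

    def iqr(x: np.ndarray) -> float:
        q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation (type 7)
        return float(q3 - q1)

    def five(x: np.ndarray) -> tuple[float, float, float, float, float]:
        if len(x) == 0:
            return (math.nan,) * 5
        return (
            float(np.mean(x)),
            float(np.mean(np.abs(x))),
            float(np.median(x)),
            float(np.median(np.abs(x))),
            iqr(x),
        )

    me, mae, mde, mdae, iqre = five(e)
    me_p, mae_p, mde_p, mdae_p, iqre_p = five(np.asarray(e_pct, dtype=float))
    return ErrorSummary(
        me=me, mae=mae, mde=mde, mdae=mdae, iqre=iqre,
        me_pct=me_p, mae_pct=mae_p, mde_pct=mde_p, mdae_pct=mdae_p, iqre_pct=iqre_p,
        n=len(e),
    )


def normality_test(e: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p; errors with p < 0.05 are treated as non-normal
    (and summarized by medians/IQR rather than means)."""
    e = np.asarray(e, dtype=float)
    if not (3 <= len(e) <= 5000):
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000; subsample larger series")
    if np.ptp(e) == 0.0:
        raise ValueError("normality test undefined for a constant sample")
    w, p = stats.shapiro(e)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------


def classify_icc(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc_2_1(data: np.ndarray, conf: float = 0.95) -> ICCResult:
    """Single-measure, absolute-agreement, two-way random-effects ICC.

    ``data`` is an (n subjects × k raters) matrix. The estimate comes from
    the two-way ANOVA mean squares

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with the F-based confidence interval of the absolute-agreement
    single-measure form.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be (n subjects × k>=2 raters)")
    n, k = x.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 subjects")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    grand = x.mean()
    if np.ptp(row_means) == 0.0:
        raise ValueError("zero between-subject variance: ICC undefined")

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (single measure, absolute agreement)
    if icc >= 1.0 - 1e-12:  # exact agreement: degenerate CI
        return ICCResult(icc=float(icc), ci_low=1.0, ci_high=1.0, icc_class="excellent")
    alpha = 1.0 - conf
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_star = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_star2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    ci_low = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_star2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star2 * msr
    )
    return ICCResult(
        icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high), icc_class=classify_icc(float(icc))
    )


def icc_sample_size(rho: float, width: float, k: int = 2, conf: float = 0.95) -> int:
    """Bouts needed so a two-rater ICC confidence interval has the target
    width (Bonett-type approximation, rounded to the nearest integer):

        n = 1 + 8·z²·(1−ρ)²·(1+(k−1)ρ)² / (k·(k−1)·w²)
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("planning ICC must lie in (0, 1)")
    if width <= 0:
        raise ValueError("CI width must be positive")
    z = stats.norm.ppf(0.5 * (1.0 + conf))
    n = 1.0 + 8.0 * z**2 * (1.0 - rho) ** 2 * (1.0 + (k - 1) * rho) ** 2 / (
        k * (k - 1) * width**2
    )
    return int(math.floor(n + 0.5))
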