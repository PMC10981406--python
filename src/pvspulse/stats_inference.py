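"""Exact small-sample inference: Wilcoxon signed-rank test and summaries.

All cohorts here are small (n ≤ 12), so the signed-rank null distribution is
computed exactly by dynamic programming over sign assignments rather than by
normal approximation.  Zero differences are dropped before ranking (the
standard convention) and tied absolute differences receive midranks, with the
null distribution computed conditional on the observed tie pattern.  The
one-tailed p-value includes the observed statistic (P(W⁺ ≤ w) for the "less"
tail), so for n paired all-negative differences p = 2⁻ⁿ.

A sign test is provided as a sensitivity alternative, along with the
percent-change and mean ± SD summaries used for cohort reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest, rankdata

__all__ = [
    "PairedSample",
    "TestResult",
    "signed_rank_test",
    "signed_rank_null_pmf",
    "sign_test",
    "percent_change",
    "cohort_summary",
]

TAILS = ("less", "greater")


@dataclass(frozen=True)
class PairedSample:
    """Index-paired pre/post measurements."""

    pre: tuple
    post: tuple
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.post):
            raise ValueError("pre and post must have equal length")
        if len(self.pre) == 0:
            raise ValueError("empty paired sample")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.post, dtype=float) - np.asarray(self.pre, dtype=float)


@dataclass(frozen=True)
class TestResult:
    """Signed-rank outcome: W⁺, effective n after zero removal, exact p."""

    statistic: float
    n_effective: int
    p_value: float
    tail: str

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def signed_rank_null_pmf(ranks: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W⁺ for the given (mid)ranks.

    Under the null each rank enters W⁺ independently with probability 1/2.
    Ranks are doubled to integers (midranks are multiples of 0.5) and the
    distribution built by convolution.  Returns (support, pmf) with support
    on the original (halved) scale.
    """
    doubled = np.asarray(np.round(np.asarray(ranks, dtype=float) * 2), dtype=int)
    if doubled.size == 0:
        raise ValueError("no ranks supplied")
    if np.any(doubled <= 0):
        raise ValueError("ranks must be positive")
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(pmf)
        shifted[d:] = pmf[:-d] if d else pmf
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(total + 1) / 2.0
    return support, pmf


def signed_rank_test(sample: PairedSample, tail: str = "less") -> TestResult:
    """Exact one-tailed Wilcoxon signed-rank test on post − pre differences.

    ``tail="less"`` tests for a decrease (post < pre), ``"greater"`` for an
    increase.  Raises if every difference is zero.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    d = sample.differences
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    support, pmf = signed_rank_null_pmf(ranks)
    if tail == "less":
        p = float(pmf[support <= w_plus + 1e-9].sum())
    else:
        p = float(pmf[support >= w_plus - 1e-9].sum())
    return TestResult(statistic=w_plus, n_effective=int(d.size),
                      p_value=min(p, 1.0), tail=tail)


def sign_test(sample: PairedSample, tail: str = "less") -> TestResult:
    """Exact binomial sign test (sensitivity alternative to the signed-rank)."""
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    d = sample.differences
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    n_pos = int((d > 0).sum())
    p = binomtest(n_pos, int(d.size), 0.5, alternative=tail).pvalue
    return TestResult(statistic=float(n_pos), n_effective=int(d.size),
                      p_value=float(p), tail=tail)


def percent_change(pre: float, post: float) -> float:
    """100·(post − pre)/pre, rounded to the nearest integer percent."""
    if pre <= 0:
        raise ValueError("baseline must be positive")
    return float(np.round(100.0 * (post - pre) / pre))


def cohort_summary(values: Sequence[float]) -> tuple[float, float]:
    """(mean, sample SD with n−1 denominator); SD is NaN for a single value."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty cohort")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return float(values.mean()), sd
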