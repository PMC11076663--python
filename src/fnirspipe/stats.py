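"""Paired-samples inference and descriptive summaries.

The paired t-test on per-participant condition scalars:

    t = mean(d) / (sd(d) / sqrt(n)),   d_i = a_i - b_i,   df = n - 1

with the two-tailed p from Student's t distribution, and the paired Cohen's
d = mean(d) / sd(d) = t / sqrt(n).  Significance threshold alpha = 0.05; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PairedTestResult", "paired_t", "cohen_d_from_t", "describe"]


@dataclass
class PairedTestResult:
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p_two_tailed: float
    cohen_d: float
    se_d: float

    def format(self, label_a: str = "A", label_b: str = "B") -> str:
        """One-line report in the conventional style."""
        p = f"{self.p_two_tailed:.3f}" if self.p_two_tailed >= 0.001 else "< 0.001"
        return (f"{label_a} (M = {self.mean_a:.4g}, SD = {self.sd_a:.4g}) vs "
                f"{label_b} (M = {self.mean_b:.4g}, SD = {self.sd_b:.4g}): "
                f"t({self.df}) = {self.t:.3f}, p = {p}, "
                f"Cohen's d = {self.cohen_d:.3f} (SE = {self.se_d:.3f})")


def paired_t(a, b) -> PairedTestResult:
    """Paired-samples t-test of condition a against condition b.

    Raises on unequal lengths, n < 2, or zero-variance differences (the t
    statistic is undefined when every pair differs by the same amount).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    mean_diff = float(d.mean())
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    cohen_d = mean_diff / sd_diff
    # SE of the paired d: first-order approximation; the sampling variance of
    # a standardized mean difference at this n is not exactly tractable.
    se_d = math.sqrt(1.0 / n + cohen_d**2 / (2.0 * n))
    return PairedTestResult(
        n=n,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        mean_diff=mean_diff, sd_diff=sd_diff,
        t=t, df=df, p_two_tailed=p, cohen_d=cohen_d, se_d=se_d,
    )


def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-design identity d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return t / math.sqrt(n)


def describe(values) -> dict:
    """Mean, sample SD (n-1 denominator) and n; SD is None at n = 1."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty input")
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else None,
        "n": int(x.size),
    }
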