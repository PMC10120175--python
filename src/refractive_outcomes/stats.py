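"""Automatic hypothesis-test dispatch, effect sizes and least-squares fits.

Two-group comparisons are dispatched on distribution shape: each sample is
first screened with a Kolmogorov-Smirnov-type normality test (Lilliefors
correction, since mean and SD are estimated from the sample).  If both
samples pass at the screening alpha the parametric branch is used
(unpaired or paired t-test); otherwise the matching rank test
(Mann-Whitney U or Wilcoxon signed-rank).  All tests are two-sided and
Cohen's d is attached regardless of branch, so the effect size is always
on the familiar mean/SD scale.

Samples too small (n < 4) or with zero variance cannot be assessed for
normality and are treated as non-normal (the conservative branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "FitResult",
    "Summary",
    "normality_p",
    "compare",
    "cohens_d",
    "linfit",
    "summarize",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one automatic two-group comparison."""

    test_name: str  # unpaired-t | mann-whitney-u | paired-t | wilcoxon-signed-rank
    statistic: float
    p_value: float
    effect_size_d: float | None  # None when not computable (zero spread)
    n_a: int
    n_b: int
    normality_p_a: float | None  # None = non-assessable
    normality_p_b: float | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")
        allowed = {"unpaired-t", "mann-whitney-u", "paired-t", "wilcoxon-signed-rank"}
        if self.test_name not in allowed:
            raise ValueError(f"unknown test {self.test_name!r}")


@dataclass(frozen=True)
class FitResult:
    """Ordinary least squares fit y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def equation(self, y: str = "y", x: str = "x", decimals: int = 3) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"{y} = {self.slope:.{decimals}f}{x} {sign} "
            f"{abs(self.intercept):.{decimals}f}"
        )


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float
    n: int


def normality_p(sample: Sequence[float]) -> float | None:
    """Lilliefors-corrected Kolmogorov-Smirnov p-value against normality.

    Tests the sample against a normal distribution with the sample's own
    mean and SD, using the small-sample correction for estimated
    parameters.  Returns None (non-assessable, treated downstream as
    non-normal) for n < 4 or zero variance.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4 or float(np.std(x, ddof=1)) == 0.0:
        return None
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def cohens_d(
    a: Sequence[float], b: Sequence[float], design: str = "unpaired"
) -> float | None:
    """Cohen's d, signed as mean(a) - mean(b).

    Unpaired: mean difference over the pooled SD (n-1 weights).  Paired:
    mean of the per-pair differences over their SD.  Returns None when the
    denominator is zero (degenerate spread).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if design == "paired":
        if xa.size != xb.size:
            raise ValueError("paired design requires equal-length samples")
        diff = xa - xb
        sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
        if sd == 0.0:
            return 0.0 if float(np.mean(diff)) == 0.0 else None
        return float(np.mean(diff) / sd)
    if design != "unpaired":
        raise ValueError(f"unknown design {design!r}")
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d needs n >= 2 per group")
    pooled_var = (
        (na - 1) * float(np.var(xa, ddof=1)) + (nb - 1) * float(np.var(xb, ddof=1))
    ) / (na + nb - 2)
    if pooled_var == 0.0:
        return 0.0 if float(np.mean(xa)) == float(np.mean(xb)) else None
    return float((np.mean(xa) - np.mean(xb)) / math.sqrt(pooled_var))


def compare(
    a: Sequence[float],
    b: Sequence[float],
    design: str = "unpaired",
    alpha: float = 0.05,
) -> StatResult:
    """Compare two samples with the design-appropriate automatic test.

    Both samples must pass the normality screen at ``alpha`` for the
    parametric branch; otherwise the rank-based test is used.  The p-value
    is two-sided.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs n >= 2")
    if design == "paired" and xa.size != xb.size:
        raise ValueError(
            f"paired comparison requires equal lengths, got {xa.size} and {xb.size}"
        )
    if design not in {"unpaired", "paired"}:
        raise ValueError(f"unknown design {design!r}")

    pa = normality_p(xa)
    pb = normality_p(xb)
    parametric = pa is not None and pb is not None and pa > alpha and pb > alpha
    d = cohens_d(xa, xb, design)

    if design == "paired":
        diff = xa - xb
        if np.all(diff == 0.0):
            # identical paired samples: no effect by construction
            name = "paired-t" if parametric else "wilcoxon-signed-rank"
            return StatResult(name, 0.0, 1.0, 0.0, xa.size, xb.size, pa, pb)
        if parametric:
            res = sps.ttest_rel(xa, xb)
            return StatResult(
                "paired-t", float(res.statistic), float(res.pvalue), d,
                xa.size, xb.size, pa, pb,
            )
        res = sps.wilcoxon(xa, xb, zero_method="wilcox", mode="auto")
        return StatResult(
            "wilcoxon-signed-rank", float(res.statistic), float(res.pvalue), d,
            xa.size, xb.size, pa, pb,
        )
    if parametric:
        res = sps.ttest_ind(xa, xb, equal_var=True)
        return StatResult(
            "unpaired-t", float(res.statistic), float(res.pvalue), d,
            xa.size, xb.size, pa, pb,
        )
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
    return StatResult(
        "mann-whitney-u", float(res.statistic), float(res.pvalue), d,
        xa.size, xb.size, pa, pb,
    )


def linfit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares line through (x, y) with R^2.

    R^2 is the squared Pearson correlation, identical to the OLS
    coefficient of determination for a line with intercept.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("linear fit needs n >= 3")
    if float(np.std(xa)) == 0.0:
        raise ValueError("x is constant; the regression is undefined")
    res = sps.linregress(xa, ya)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=int(xa.size),
    )


def summarize(sample: Sequence[float]) -> Summary:
    """Arithmetic mean, sample SD (n-1) and count; SD is 0 for n = 1."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return Summary(mean=float(np.mean(x)), sd=sd, n=int(x.size))
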