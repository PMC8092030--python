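"""Between-phase comparison of normalized emotion intensities.

Each emotion's normalized intensity is treated as a proportion *p* of *n*
emotion observations.  Two phases are compared per emotion with

* a Pearson chi-square test (2×2, df=1, no continuity correction) on
  counts reconstructed as ``round(p·n)``, and
* a 95% confidence interval for the difference of the two proportions by
  the Newcombe hybrid score method: the interval is assembled from the two
  single-sample Wilson score intervals,

  .. math::

     d - \\sqrt{(p_A-l_A)^2 + (u_B-p_B)^2}
     \\;\\le\\; p_A - p_B \\;\\le\\;
     d + \\sqrt{(u_A-p_A)^2 + (p_B-l_B)^2}

  with A the larger proportion, so differences are reported as positive
  percentage points regardless of direction.

The normal quantile is the exact value (z = 1.959964 at 95%), not 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .intensity import IntensityProfile
from .plutchik import EMOTIONS

__all__ = ["ProportionSample", "ComparisonResult", "wilson_interval",
           "newcombe_difference_ci", "chisq_two_proportions",
           "compare_intensity_profiles", "comparison_table"]


@dataclass(frozen=True)
class ProportionSample:
    """An observed proportion p out of n observations."""

    p: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass
class ComparisonResult:
    emotion: str
    p1: float
    n1: int
    p2: float
    n2: int
    diff: float  # absolute difference, percentage points
    ci_low: float  # percentage points
    ci_high: float
    chi2: float
    df: int
    p_value: float
    significant: bool


def wilson_interval(p: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a single proportion.

    Inverts the score test: bounds are
    ``(p + z²/2n ∓ z·√(p(1−p)/n + z²/4n²)) / (1 + z²/n)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    z = sps.norm.ppf(0.5 + conf / 2.0)
    z2 = z * z
    center = p + z2 / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
    denom = 1 + z2 / n
    return (center - half) / denom, (center + half) / denom


def newcombe_difference_ci(
    s1: ProportionSample,
    s2: ProportionSample,
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """Newcombe hybrid-score CI for the difference of two proportions.

    Returns ``(diff, ci_low, ci_high)`` in percentage points, oriented so
    the difference is the larger proportion minus the smaller one.
    """
    if s1.p >= s2.p:
        hi, lo = s1, s2
    else:
        hi, lo = s2, s1
    d = hi.p - lo.p
    l_a, u_a = wilson_interval(hi.p, hi.n, conf)
    l_b, u_b = wilson_interval(lo.p, lo.n, conf)
    ci_low = d - math.sqrt((hi.p - l_a) ** 2 + (u_b - lo.p) ** 2)
    ci_high = d + math.sqrt((u_a - hi.p) ** 2 + (lo.p - l_b) ** 2)
    return 100.0 * d, 100.0 * ci_low, 100.0 * ci_high


def chisq_two_proportions(
    s1: ProportionSample,
    s2: ProportionSample,
) -> tuple[float, float]:
    """Pearson chi-square test (df=1, no continuity correction).

    2×2 counts are reconstructed as ``round(p·n)`` successes per sample.
    Returns ``(chi2, p_value)``; identical proportions give (0, 1).
    """
    a = round(s1.p * s1.n)
    c = round(s2.p * s2.n)
    b = s1.n - a
    d = s2.n - c
    if min(a, b, c, d) < 0:
        raise ValueError("reconstructed cell count is negative")
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p_value = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p_value


def compare_intensity_profiles(
    prof1: IntensityProfile,
    prof2: IntensityProfile,
    alpha: float = 0.05,
    conf: float = 0.95,
) -> list[ComparisonResult]:
    """Emotion-by-emotion comparison of two phase profiles.

    Each emotion's normalized intensity becomes a proportion of the
    profile's ``n_observations``; the chi-square test and Newcombe CI are
    applied per emotion.  Returns one result per emotion in canonical
    order.
    """
    results = []
    for emo in EMOTIONS:
        s1 = ProportionSample(prof1.proportion(emo), prof1.n_observations)
        s2 = ProportionSample(prof2.proportion(emo), prof2.n_observations)
        diff, lo, hi = newcombe_difference_ci(s1, s2, conf)
        chi2, p_value = chisq_two_proportions(s1, s2)
        results.append(ComparisonResult(
            emotion=emo, p1=s1.p, n1=s1.n, p2=s2.p, n2=s2.n,
            diff=diff, ci_low=lo, ci_high=hi,
            chi2=chi2, df=1, p_value=p_value,
            significant=p_value < alpha,
        ))
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Serialize comparison results in the published-table layout."""
    rows = [{
        "emotion": r.emotion,
        "p1_pct": 100 * r.p1, "p2_pct": 100 * r.p2,
        "diff_pct": r.diff, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "chi2": r.chi2, "p_value": r.p_value, "significant": r.significant,
    } for r in results]
    return pd.DataFrame(rows, columns=["emotion", "p1_pct", "p2_pct",
                                       "diff_pct", "ci_low", "ci_high",
                                       "chi2", "p_value", "significant"])
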