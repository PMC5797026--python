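"""Subgroup-versus-rest categorical statistics.

Proportions carry Wald intervals on the percent scale (clamped to [0, 100]);
odds ratios carry Woolf log-normal intervals; association p-values come from
the Pearson chi-square without continuity correction.  These are the
conventional choices for reporting remission and transplant rates by genomic
subgroup.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "EstimateMethod",
    "RatioEstimate",
    "proportion_with_ci",
    "odds_ratio",
    "chi_square",
    "subgroup_vs_rest",
]


class TwoByTwo(NamedTuple):
    """a = event-in-group, b = no-event-in-group, c = event-in-rest, d = rest."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if any(x < 0 for x in self):
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both rows must have positive totals")


class EstimateMethod(str, Enum):
    WOOLF_OR = "woolf_or"
    WALD_PROP = "wald_prop"
    CHI2 = "chi2"


@dataclass(frozen=True)
class RatioEstimate:
    point: float
    ci_low: float
    ci_high: float
    p_value: float | None
    method: EstimateMethod
    corrected: bool = False  # Haldane-Anscombe +0.5 applied

    def __post_init__(self) -> None:
        assert self.ci_low <= self.point + 1e-12
        assert self.point <= self.ci_high + 1e-12


def _z(level: float) -> float:
    return float(sps.norm.ppf(0.5 + level / 2.0))


def proportion_with_ci(k: int, n: int, level: float = 0.95) -> RatioEstimate:
    """Percent-scale proportion with a Wald interval clamped to [0, 100]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    point = 100.0 * p
    half = _z(level) * 100.0 * math.sqrt(p * (1.0 - p) / n)
    return RatioEstimate(
        point=point,
        ci_low=max(0.0, point - half),
        ci_high=min(100.0, point + half),
        p_value=None,
        method=EstimateMethod.WALD_PROP,
    )


def chi_square(t: TwoByTwo) -> float:
    """Pearson chi-square p (1 df, no continuity correction)."""
    t.validate()
    n = sum(t)
    if n == 0:
        raise ValueError("empty table")
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if c1 == 0 or c2 == 0:
        return 1.0
    expected = [r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n]
    if min(expected) < 1:
        warnings.warn(
            "expected cell count < 1; consider the exact test", stacklevel=2
        )
    stat = sum((o - e) ** 2 / e for o, e in zip(t, expected))
    return float(sps.chi2.sf(stat, df=1))


def odds_ratio(t: TwoByTwo, level: float = 0.95) -> RatioEstimate:
    """Odds ratio with a Woolf (log-normal) interval and a chi-square p.

    Tables with a zero cell get the Haldane-Anscombe +0.5 correction in every
    cell (the estimate is tagged ``corrected``); the chi-square p is always
    computed on the uncorrected table.
    """
    t.validate()
    p_value = chi_square(t)
    corrected = 0 in t
    a, b, c, d = ((x + 0.5 for x in t) if corrected else t)
    point = (a * d) / (b * c)
    half = _z(level) * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(point)
    return RatioEstimate(
        point=point,
        ci_low=math.exp(log_or - half),
        ci_high=math.exp(log_or + half),
        p_value=p_value,
        method=EstimateMethod.WOOLF_OR,
        corrected=corrected,
    )


def subgroup_vs_rest(k_group: int, n_group: int, k_rest: int, n_rest: int) -> dict:
    """Convenience bundle: group rate, rest rate, OR and p for one endpoint."""
    table = TwoByTwo(k_group, n_group - k_group, k_rest, n_rest - k_rest)
    orr = odds_ratio(table)
    return {
        "rate_group": proportion_with_ci(k_group, n_group),
        "rate_rest": proportion_with_ci(k_rest, n_rest),
        "odds_ratio": orr,
        "p_value": orr.p_value,
    }
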