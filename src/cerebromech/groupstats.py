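"""Normality-gated two-group comparison and summary reporting.

Each group is tested for normality with Shapiro-Wilk at alpha = 0.05; if
both pass, a two-sided pooled-variance independent t-test compares the
groups, otherwise a two-sided Mann-Whitney U test.  (One non-normal group
is enough to fall back to Mann-Whitney — the conservative reading.)
Summaries are mean +/- SEM by default, mean +/- SD where a table reports
SD; report strings round to one decimal, half away from zero.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

NORMALITY_ALPHA = 0.05


class GroupStatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    shapiro_p_a: float
    shapiro_p_b: float
    test: str  # "t" or "mannwhitney"
    statistic: float
    pvalue: float
    significant: bool
    mean_a: float
    mean_b: float


@dataclass
class Summary:
    mean: float
    dispersion: float | None  # SD or SEM depending on mode; None if n < 2
    mode: str
    n: int

    def __str__(self) -> str:
        if self.dispersion is None:
            return _round1(self.mean)
        return f"{_round1(self.mean)} ± {_round1(self.dispersion)}"


def _round1(x: float) -> str:
    """One decimal, half away from zero (table formatting convention)."""
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return str(d)


def compare(group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05) -> GroupComparison:
    """Shapiro-Wilk-gated two-sided comparison of two independent groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise GroupStatsError("each group needs n >= 3 (normality untestable below)")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    if sw_a >= NORMALITY_ALPHA and sw_b >= NORMALITY_ALPHA:
        res = stats.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitney"
    p = float(res.pvalue)
    return GroupComparison(
        shapiro_p_a=float(sw_a),
        shapiro_p_b=float(sw_b),
        test=test,
        statistic=float(res.statistic),
        pvalue=p,
        significant=p < alpha,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def summarize(values: Sequence[float], mode: str = "sem") -> Summary:
    """Mean with SD (n-1 denominator) or SEM = SD/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise GroupStatsError("need at least one value")
    if mode not in ("sem", "sd"):
        raise ValueError(f"mode must be 'sem' or 'sd', got {mode!r}")
    if v.size < 2:
        return Summary(mean=float(v.mean()), dispersion=None, mode=mode, n=int(v.size))
    sd = float(v.std(ddof=1))
    disp = sd / np.sqrt(v.size) if mode == "sem" else sd
    return Summary(mean=float(v.mean()), dispersion=float(disp), mode=mode, n=int(v.size))
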