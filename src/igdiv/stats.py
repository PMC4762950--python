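"""Statistical comparisons for the diversification assays.

Two-proportion z-test for mutation-event frequencies (events over base pairs
sequenced behave as proportions of two independent groups), Mann-Whitney for
median GFP-loss comparisons, one- and two-tailed t tests for expression and
genome-wide elongation-index data, the GFP-loss fluctuation summary with its
>50% exclusion rule, and RT-PCR relative expression normalized to a
housekeeping reference (Rab7a in the DT40 assays).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "FluctuationSample",
    "two_proportion_z",
    "mann_whitney",
    "t_test",
    "gfp_loss_summary",
    "relative_expression",
    "significance_stars",
]

GFP_LOSS_EXCLUSION = 50.0  # percent; higher values were GFP- at subcloning time


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    method: str  # exact / normal-approximation / welch / pooled / degenerate
    group_summaries: dict = field(default_factory=dict)
    fold_change: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class FluctuationSample:
    """Per-subclone GFP-negative percentages for one cell line.

    Values above the exclusion threshold are dropped on construction: a
    subclone already >50% GFP-negative was likely GFP-negative when subcloned,
    so it measures the starting state, not fluctuation.
    """

    label: str
    values: list[float]
    excluded: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 100.0 for v in self.values):
            raise ValueError(f"{self.label}: percentages must be in [0, 100]")
        kept = [v for v in self.values if v <= GFP_LOSS_EXCLUSION]
        self.excluded = [v for v in self.values if v > GFP_LOSS_EXCLUSION]
        self.values = kept

    @property
    def median(self) -> float:
        if not self.values:
            raise ValueError(f"{self.label}: all values excluded (>50% GFP loss)")
        return float(np.median(self.values))


def two_proportion_z(
    events1: int, n1: int, events2: int, n2: int,
    alternative: str = "two-sided",
    continuity: bool = False,
) -> ComparisonResult:
    """Pooled two-proportion z-test on event counts over bp sequenced.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p pooled. Degenerate
    pooled proportions (0 or 1) carry no evidence either way: p-value 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be > 0")
    if not (0 <= events1 <= n1 and 0 <= events2 <= n2):
        raise ValueError("event counts must lie in [0, n]")
    p1, p2 = events1 / n1, events2 / n2
    pooled = (events1 + events2) / (n1 + n2)
    summaries = {
        "group1": {"events": events1, "n": n1, "freq": p1},
        "group2": {"events": events2, "n": n2, "freq": p2},
    }
    if pooled in (0.0, 1.0):
        return ComparisonResult("two-proportion z", 0.0, 1.0, "degenerate", summaries)
    diff = p1 - p2
    if continuity:
        corr = 0.5 * (1 / n1 + 1 / n2)
        diff = math.copysign(max(abs(diff) - corr, 0.0), diff)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = diff / se
    if alternative == "two-sided":
        p = 2 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    fold = (p1 / p2) if p2 > 0 else None
    return ComparisonResult("two-proportion z", float(z), float(min(p, 1.0)),
                            "normal-approximation", summaries, fold)


def mann_whitney(
    group_a: list[float], group_b: list[float], alternative: str = "two-sided"
) -> ComparisonResult:
    """Mann-Whitney U with mid-rank ties.

    Exact p by enumeration when the smaller group has <= 8 values and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 value")
    summaries = {
        "group1": {"n": int(a.size), "median": float(np.median(a))},
        "group2": {"n": int(b.size), "median": float(np.median(b))},
    }
    if np.all(a == a[0]) and np.all(b == a[0]):
        return ComparisonResult("Mann-Whitney", float(a.size * b.size / 2), 1.0,
                                "degenerate", summaries)
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact = min(a.size, b.size) <= 8 and not ties
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return ComparisonResult(
        "Mann-Whitney", float(res.statistic), float(res.pvalue),
        "exact" if exact else "normal-approximation", summaries,
    )


def t_test(
    group_a: list[float], group_b: list[float],
    tails: int = 2,
    equal_variance: bool = False,
    direction: str = "greater",
) -> ComparisonResult:
    """Student (pooled) or Welch t test, one- or two-tailed.

    One-tailed tests must declare their direction ('greater' means group A is
    hypothesized larger). Zero variance with equal means gives p = 1; with
    unequal means the p-value underflows toward 0 and is flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if tails == 1 and direction not in ("greater", "less"):
        raise ValueError("one-tailed test requires direction 'greater' or 'less'")
    summaries = {
        "group1": {"n": int(a.size), "mean": float(a.mean())},
        "group2": {"n": int(b.size), "mean": float(b.mean())},
    }
    method = "pooled" if equal_variance else "welch"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult("t", 0.0, 1.0, "degenerate", summaries)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return ComparisonResult("t", sign * math.inf, 0.0, "degenerate", summaries)
    alternative = "two-sided" if tails == 2 else direction
    res = sps.ttest_ind(a, b, equal_var=equal_variance, alternative=alternative)
    fold = (a.mean() / b.mean()) if b.mean() > 0 and a.mean() > 0 else None
    return ComparisonResult(f"t {tails}-tailed", float(res.statistic),
                            float(res.pvalue), method, summaries, fold)


def gfp_loss_summary(
    samples: list[FluctuationSample],
    pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Fluctuation-assay summary: medians, fold-stimulations, Mann-Whitney.

    ``pairs`` designates (numerator, denominator) labels for fold-stimulation
    (e.g. DIVAC-containing over DIVAC-less); by default every sample is
    compared to the first. Each pair also gets a two-sided Mann-Whitney test
    on the retained values.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    by_label = {s.label: s for s in samples}
    medians = {s.label: s.median for s in samples}  # raises if all excluded
    exclusions = {s.label: len(s.excluded) for s in samples}
    if pairs is None:
        base = samples[0].label
        pairs = [(s.label, base) for s in samples[1:]]
    folds = {}
    tests = {}
    for num, den in pairs:
        sn, sd = by_label[num], by_label[den]
        folds[(num, den)] = (medians[num] / medians[den]) if medians[den] > 0 else math.inf
        tests[(num, den)] = mann_whitney(sn.values, sd.values)
    return {"medians": medians, "exclusions": exclusions,
            "fold_stimulation": folds, "mann_whitney": tests}


def relative_expression(
    target_signal: list[float] | float,
    reference_signal: list[float] | float,
    baseline_target: list[float] | float,
    baseline_reference: list[float] | float,
) -> dict:
    """RT-PCR relative expression: target normalized to a housekeeping
    reference, then expressed as fold over the baseline line's normalized
    value. Replicate measurements are averaged before taking ratios."""
    def mean(x):
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        return float(arr.mean())

    ref = mean(reference_signal)
    bref = mean(baseline_reference)
    if ref <= 0 or bref <= 0:
        raise ValueError("reference signals must be > 0")
    normalized = mean(target_signal) / ref
    baseline_normalized = mean(baseline_target) / bref
    fold = normalized / baseline_normalized if baseline_normalized > 0 else math.inf
    return {"normalized": normalized, "baseline_normalized": baseline_normalized,
            "fold_vs_baseline": fold}
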