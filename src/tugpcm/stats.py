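"""Disability classification and group-comparison statistics.

Functional disability is operationalised as meeting at least two of five
indicators: poor self-reported health, handgrip strength below the
sex-specific cut-off (27 kg men / 16 kg women), one-leg stance under 10 s,
Barthel index below 20 (basic ADL limitation) and Lawton-Brody score below
23 (instrumental ADL limitation).

Group comparisons follow the conventions of the source analysis: normality
is screened with Shapiro-Wilk (smaller group) and Lilliefors-corrected
Kolmogorov-Smirnov (larger group); parametric comparisons use the
pooled-variance t test, non-parametric ones the Mann-Whitney U test
(U reported as min(U1, U2)); 2x2 categorical associations use the Pearson
chi-square, with Yates continuity correction available behind a flag; effect
sizes are Cohen's d from group means and the pooled standard deviation, with
a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "HANDGRIP_CUTOFF_KG",
    "DisabilityIndicators",
    "ComparisonResult",
    "classify_disability",
    "chi_square_2x2",
    "pooled_t_from_summary",
    "mann_whitney_u",
    "cohens_d",
    "cohens_d_from_summary",
    "normality_gate",
    "compare_groups",
    "compare_pc_scores",
]

HANDGRIP_CUTOFF_KG = {"male": 27.0, "female": 16.0}
ONE_LEG_STANCE_CUTOFF_S = 10.0
BARTHEL_CUTOFF = 20
LAWTON_CUTOFF = 23


@dataclass(frozen=True)
class DisabilityIndicators:
    """The five disability-indicator measurements for one subject."""

    self_reported_health: str  # "good" or "poor"
    sex: str  # "male" or "female"
    handgrip_kg: float
    one_leg_stance_s: float  # 0-60, capped at 60 by protocol
    barthel: int  # 0-20
    lawton: int  # 0-23

    def __post_init__(self) -> None:
        if self.self_reported_health not in ("good", "poor"):
            raise ValueError(f"self_reported_health must be good/poor, got "
                             f"{self.self_reported_health!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if not 0 <= self.one_leg_stance_s <= 60:
            raise ValueError("one_leg_stance_s must be in [0, 60]")
        if not 0 <= self.barthel <= 20:
            raise ValueError("barthel must be in [0, 20]")
        if not 0 <= self.lawton <= 23:
            raise ValueError("lawton must be in [0, 23]")


@dataclass(frozen=True)
class ComparisonResult:
    """One group comparison: test statistic, p-value and effect size."""

    name: str
    statistic_name: str  # "U", "t" or "chi2"
    statistic_value: float
    p_value: float
    effect_size_d: float
    d_ci_low: float
    d_ci_high: float
    n_group1: int
    n_group2: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if not self.d_ci_low <= self.effect_size_d <= self.d_ci_high:
            raise ValueError("effect-size CI does not bracket d")


def classify_disability(ind: DisabilityIndicators) -> tuple:
    """Return ("D" or "ND", number of indicators met).

    "D" (functional disability) requires at least two of the five indicators.
    The rule is monotone: worsening any indicator can only increase the count.
    """
    count = sum(
        (
            ind.self_reported_health == "poor",
            ind.handgrip_kg < HANDGRIP_CUTOFF_KG[ind.sex],
            ind.one_leg_stance_s < ONE_LEG_STANCE_CUTOFF_S,
            ind.barthel < BARTHEL_CUTOFF,
            ind.lawton < LAWTON_CUTOFF,
        )
    )
    return ("D" if count >= 2 else "ND", count)


def chi_square_2x2(a: int, b: int, c: int, d: int, continuity: bool = False) -> tuple:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]].

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with ``continuity``,
    |ad - bc| is reduced by n/2 (floored at 0) before squaring.  Returns
    (chi2, p) with df = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or 0 in margins:
        raise ValueError("chi-square undefined: zero marginal total")
    det = abs(a * d - b * c)
    if continuity:
        det = max(0.0, det - n / 2.0)
    chi2 = n * det**2 / np.prod([float(m) for m in margins])
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple:
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, p) with df = n1 + n2 - 2 and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df, float(2 * sps.t.sf(abs(t), df))


def mann_whitney_u(sample1: Sequence[float], sample2: Sequence[float]) -> tuple:
    """Mann-Whitney U with midranks for ties; returns (U, p).

    U is reported as min(U1, U2), matching the convention of mainstream
    statistical software.  The p-value is exact (full enumeration) for
    combined samples of 12 or fewer observations without ties, otherwise the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    df = x.size + y.size - 2
    return float(
        np.sqrt(((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df)
    )


def cohens_d_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple:
    """Cohen's d from group summaries with a 95% normal-approximation CI.

    d = (mean1 - mean2) / pooled SD;
    SE(d) = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise ZeroDivisionError("zero pooled standard deviation")
    d = float((mean1 - mean2) / sp)
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))))
    z = sps.norm.ppf(0.975)
    return d, d - z * se, d + z * se


def cohens_d(sample1: Sequence[float], sample2: Sequence[float]) -> tuple:
    """Cohen's d (pooled SD) between two raw samples; returns (d, lo, hi)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    return cohens_d_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def normality_gate(sample1, sample2, alpha: float = 0.05) -> str:
    """Decide between parametric and non-parametric group comparison.

    Shapiro-Wilk tests the smaller group, the Lilliefors-corrected
    Kolmogorov-Smirnov test the larger one; the comparison is "parametric"
    only when both normality tests are non-significant at ``alpha``.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("normality screening needs >= 3 observations per group")
    small, large = (x, y) if x.size <= y.size else (y, x)
    p_small = sps.shapiro(small).pvalue if np.ptp(small) > 0 else 0.0
    if np.ptp(large) == 0:
        p_large = 0.0
    elif large.size < 4:  # below the Lilliefors minimum
        p_large = sps.shapiro(large).pvalue
    else:
        p_large = lilliefors(large, dist="norm")[1]
    return "parametric" if (p_small > alpha and p_large > alpha) else "nonparametric"


def compare_groups(sample1, sample2, name: str = "", alpha: float = 0.05,
                   force: str | None = None) -> ComparisonResult:
    """Normality-gated two-group comparison with effect size.

    ``force`` overrides the gate ("parametric" or "nonparametric"); the
    component-score comparisons use ``force="nonparametric"`` to mirror the
    Mann-Whitney convention of the source analysis.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("a group is empty")
    route = force or normality_gate(x, y, alpha)
    if route == "parametric":
        t, _, p = pooled_t_from_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
        )
        stat_name, stat = "t", t
    elif route == "nonparametric":
        stat, p = mann_whitney_u(x, y)
        stat_name = "U"
    else:
        raise ValueError(f"unknown comparison route {route!r}")
    if np.array_equal(np.sort(x), np.sort(y)):
        d, lo, hi = 0.0, 0.0, 0.0
        se = np.sqrt((x.size + y.size) / (x.size * y.size))
        lo, hi = -1.959963984540054 * se, 1.959963984540054 * se
    else:
        d, lo, hi = cohens_d(x, y)
    return ComparisonResult(
        name=name, statistic_name=stat_name, statistic_value=float(stat),
        p_value=float(p), effect_size_d=float(d), d_ci_low=float(lo),
        d_ci_high=float(hi), n_group1=x.size, n_group2=y.size,
    )


def compare_pc_scores(scores: pd.DataFrame, group_labels: pd.Series,
                      holm: bool = False) -> pd.DataFrame:
    """Mann-Whitney comparison of every component score between groups.

    Parameters
    ----------
    scores : DataFrame
        Subjects x components (index = subject_id).
    group_labels : Series
        "ND"/"D" per subject_id; must cover every scored subject.
    holm : bool
        If True, add a Holm-adjusted p-value column.  Off by default — the
        source analysis reports the 11 component tests unadjusted.

    Returns a DataFrame with one row per component: U, p, Cohen's d and CI.
    """
    labels = group_labels.reindex(scores.index)
    if labels.isna().any():
        missing = scores.index[labels.isna()].tolist()
        raise ValueError(f"no group label for subject(s): {missing}")
    nd = scores.loc[labels == "ND"]
    dd = scores.loc[labels == "D"]
    if len(nd) == 0 or len(dd) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for comp in scores.columns:
        res = compare_groups(
            nd[comp].to_numpy(), dd[comp].to_numpy(),
            name=str(comp), force="nonparametric",
        )
        rows.append(
            {
                "component": comp,
                "U": res.statistic_value,
                "p_value": res.p_value,
                "cohens_d": res.effect_size_d,
                "d_ci_low": res.d_ci_low,
                "d_ci_high": res.d_ci_high,
                "n_nd": res.n_group1,
                "n_d": res.n_group2,
            }
        )
    out = pd.DataFrame(rows).set_index("component")
    if holm:
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out
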