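"""Normalization, summaries and hypothesis tests for the imaging readouts.

The analysis design is classical: per-cell (or per-experiment) values,
control normalization within each experiment, means +/- SEM, two-tailed
Student's t-test for two groups, one-way ANOVA with Bonferroni-corrected
post-hoc t-tests for more.  Significance is declared at alpha = 0.05 on the
adjusted p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


@dataclass
class GroupSummary:
    """Mean +/- SEM for one group; SEM uses the n-1 sample SD over sqrt(n)."""

    label: str
    n: int
    mean: float
    sem: float  # NaN when n == 1 (undefined, reported as missing)
    normalized_mean: float | None = None


@dataclass
class ComparisonResult:
    """One hypothesis test, with its Bonferroni-adjusted p-value.

    ``family_size`` is the number of comparisons the adjustment divides alpha
    across; ``p_adjusted = min(1, p_raw * family_size)`` and ``significant``
    means ``p_adjusted < alpha``.
    """

    test: str  # "t_two_tailed" | "anova_oneway"
    groups: tuple[str, ...]
    statistic: float
    df: float | tuple[float, float]
    p_raw: float
    p_adjusted: float
    family_size: int
    significant: bool
    alpha: float = ALPHA_DEFAULT


@dataclass
class AnovaBonferroniResult:
    anova: ComparisonResult
    pairwise: list[ComparisonResult] = field(default_factory=list)


def normalize_to_control(
    data: pd.DataFrame,
    control_label: str,
    group_col: str = "group",
    value_col: str = "value",
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Divide every value by its experiment's control mean.

    This is the normalize-then-average design: within each experiment all
    groups are scaled so the control group's mean is exactly 1.0, making
    experiments comparable before averaging.  A missing or zero-mean control
    in any experiment is an error naming that experiment.
    """
    out = data.copy()
    out["normalized"] = np.nan
    for exp, sub in data.groupby(experiment_col):
        ctrl = sub.loc[sub[group_col] == control_label, value_col]
        if ctrl.empty:
            raise ValueError(f"experiment {exp!r}: control group {control_label!r} missing")
        ref = float(ctrl.mean())
        if ref == 0 or not math.isfinite(ref):
            raise ValueError(f"experiment {exp!r}: control mean is zero or non-finite")
        out.loc[sub.index, "normalized"] = sub[value_col] / ref
    return out


def summarize(values, label: str = "") -> GroupSummary:
    """Mean and SEM of a group of values (n >= 1; SEM missing for n = 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sem = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()), sem=sem)


def t_test_two_tailed(
    a,
    b,
    variance: str = "pooled",
    family_size: int = 1,
    alpha: float = ALPHA_DEFAULT,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-tailed two-sample t-test (Student pooled-variance or Welch).

    Zero variance in both groups with equal means yields t = 0, p = 1 rather
    than an error.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance model {variance!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
        df: float = a.size + b.size - 2
    else:
        res = sps.ttest_ind(a, b, equal_var=(variance == "pooled"))
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    p_adj = min(1.0, p * family_size)
    return ComparisonResult(
        test="t_two_tailed",
        groups=labels,
        statistic=t,
        df=df,
        p_raw=p,
        p_adjusted=p_adj,
        family_size=family_size,
        significant=p_adj < alpha,
        alpha=alpha,
    )


def _anova_oneway(groups: dict[str, np.ndarray], alpha: float) -> ComparisonResult:
    arrs = list(groups.values())
    k = len(arrs)
    n_tot = sum(a.size for a in arrs)
    df = (float(k - 1), float(n_tot - k))
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0  # all values identical
    else:
        res = sps.f_oneway(*arrs)
        f, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test="anova_oneway",
        groups=tuple(groups),
        statistic=f,
        df=df,
        p_raw=p,
        p_adjusted=p,
        family_size=1,
        significant=p < alpha,
        alpha=alpha,
    )


def anova_bonferroni(
    groups: dict[str, object],
    family: str,
    reference: str | None = None,
    variance: str = "pooled",
    alpha: float = ALPHA_DEFAULT,
) -> AnovaBonferroniResult:
    """One-way ANOVA followed by Bonferroni-corrected pairwise t-tests.

    ``family`` is a required choice because the comparison family differs by
    design: ``"vs_reference"`` compares every group against ``reference``
    (family size g-1, e.g. ring 1 as the perinuclear reference), while
    ``"all_pairs"`` compares every pair (family size g(g-1)/2).
    """
    clean = {str(k): np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for lab, arr in clean.items():
        if arr.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")
    if family not in ("vs_reference", "all_pairs"):
        raise ValueError(f"unknown family {family!r}; use 'vs_reference' or 'all_pairs'")
    if family == "vs_reference":
        if reference is None or str(reference) not in clean:
            raise ValueError(
                f"reference group {reference!r} not among {sorted(clean)}"
            )
        pairs = [(str(reference), lab) for lab in clean if lab != str(reference)]
    else:
        pairs = list(combinations(clean, 2))
    m = len(pairs)
    anova = _anova_oneway(clean, alpha)
    pairwise = [
        t_test_two_tailed(
            clean[x], clean[y], variance=variance, family_size=m, alpha=alpha,
            labels=(x, y),
        )
        for x, y in pairs
    ]
    return AnovaBonferroniResult(anova=anova, pairwise=pairwise)
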