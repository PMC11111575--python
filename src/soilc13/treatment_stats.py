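"""Treatment-level summaries and comparisons: means ± SE, one-way ANOVA
with assumption checks (Shapiro–Wilk on residuals, Levene across groups),
Tukey HSD with a compact letter display, and fold changes vs control.
Comparisons are intended per sampling date; callers loop over days."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupSummary:
    group: tuple | str
    n: int
    mean: float
    se: float | None  # undefined (None) when n < 2


@dataclass
class ComparisonResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    shapiro_p: float | None
    levene_p: float | None
    tukey: pd.DataFrame | None = None
    letters: dict | None = None
    warnings: list[str] = field(default_factory=list)


def summarize(groups: dict) -> list[GroupSummary]:
    """Mean and standard error of the mean (sd/√n) per group."""
    out = []
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else None
        out.append(GroupSummary(group=name, n=int(v.size), mean=float(v.mean()), se=se))
    return out


def anova_oneway(groups: dict) -> ComparisonResult:
    """Classical one-way ANOVA across ≥ 2 groups, with assumption checks.

    Raises when the within-group variance is zero while group means differ
    (F undefined). Assumption-check failures are reported as warnings, not
    acted on — no automatic nonparametric fallback.
    """
    names = list(groups)
    arrays = [np.asarray(list(groups[k]), dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")

    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    if ssw == 0:
        if ssb == 0:
            f, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance with unequal means: F undefined")
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    residuals = np.concatenate([a - a.mean() for a in arrays])
    warnings = []
    shapiro_p = levene_p = None
    if np.ptp(residuals) > 0:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
        if shapiro_p < 0.05:
            warnings.append(f"residual normality questionable (Shapiro–Wilk p = {shapiro_p:.3g})")
    if all(np.ptp(a) > 0 for a in arrays):
        levene_p = float(stats.levene(*arrays).pvalue)
        if levene_p < 0.05:
            warnings.append(f"variance homogeneity questionable (Levene p = {levene_p:.3g})")

    return ComparisonResult(
        f_statistic=float(f), df_between=df_b, df_within=df_w, p_value=float(p),
        shapiro_p=shapiro_p, levene_p=levene_p, warnings=warnings,
    )


def tukey_hsd(groups: dict, alpha: float = 0.05) -> ComparisonResult:
    """Tukey HSD pairwise comparisons plus a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie strictly between 0 and 1, got {alpha}")
    result = anova_oneway(groups)
    names = list(groups)
    values = np.concatenate([np.asarray(list(groups[k]), dtype=float) for k in names])
    labels = np.concatenate([[str(k)] * len(list(groups[k])) for k in names])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    sig = {}
    for _, row in table.iterrows():
        sig[frozenset((row["group1"], row["group2"]))] = bool(row["reject"])
    means = {str(k): float(np.mean(list(groups[k]))) for k in names}
    result.tukey = table
    result.letters = compact_letters([str(k) for k in names], sig, means)
    return result


def compact_letters(names: list[str], significant: dict, means: dict) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` maps frozenset({g1, g2}) → bool. Letters are assigned
    in order of decreasing group mean; groups sharing a letter are not
    significantly different.
    """
    order = sorted(names, key=lambda g: -means.get(g, 0.0))
    columns: list[set] = [set(order)]
    for g1, g2 in [(a, b) for i, a in enumerate(order) for b in order[i + 1:]]:
        if not significant.get(frozenset((g1, g2)), False):
            continue
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                columns.append(col - {g1})
                columns.append(col - {g2})
        # absorb columns contained in another
        keep = []
        for col in columns:
            if not any(col < other for other in columns if other is not col):
                keep.append(col)
        # dedupe
        columns = []
        for col in keep:
            if col not in columns:
                columns.append(col)
    columns.sort(key=lambda col: min(order.index(g) for g in col) if col else len(order))
    letters = {g: "" for g in names}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def fold_change(treatment_mean: float, control_mean: float) -> float:
    """Ratio of treatment to control mean; full precision (round for display)."""
    if control_mean == 0:
        raise ValueError("control mean is zero: fold change undefined")
    return treatment_mean / control_mean
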