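"""Group-difference screen: one-way ANOVA, Student-Newman-Keuls post hoc,
and compact letter display.

Each outcome (a region's c-Fos density, or any scalar behavioral measure)
is screened with a classical fixed-effects one-way ANOVA across conditions.
When the omnibus test is significant, pairwise differences are assessed
with the SNK step-down procedure on the Studentized range distribution:
means are ordered, the widest span is tested first, and any pair lying
inside a span already declared homogeneous is forced non-significant. The
resulting significance relation is rendered as the familiar "a / ab / b"
letter codes, where sharing any letter means no significant difference.

With unequal group sizes the SNK denominator uses the harmonic mean of the
two compared groups' sizes. No multiple-testing correction is applied
across outcomes; downstream tables carry an explicit caveat flag instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import StudyDataset


@dataclass(frozen=True)
class GroupSamples:
    """One outcome's values, grouped by condition label."""

    outcome_name: str
    groups: dict[str, np.ndarray]

    def __init__(self, outcome_name: str, groups: dict):
        object.__setattr__(self, "outcome_name", str(outcome_name))
        object.__setattr__(
            self, "groups", {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
        )
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for label, vals in self.groups.items():
            if vals.ndim != 1 or len(vals) < 2:
                raise ValueError(f"group {label!r} needs at least 2 values")
            if np.isnan(vals).any():
                raise ValueError(f"group {label!r} contains NaN")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    ms_within: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_statistic: float
    span_r: int
    p: float
    significant: bool
    blocked: bool = False  # forced non-significant by the step-down rule


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter codes: groups share a letter iff not significantly different."""

    letters: dict[str, str] = field(default_factory=dict)

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def one_way_anova(samples: GroupSamples) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    All values identical everywhere yields F = 0, p = 1 (no evidence of any
    difference) rather than an error; zero within-group variance with
    distinct means yields F = inf, p = 0.
    """
    groups = samples.groups
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    k = len(groups)
    N = len(values)

    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, N - k
    means = {g: float(v.mean()) for g, v in groups.items()}
    ms_w = ss_within / df_w

    if ss_within == 0.0:
        if math.isclose(ss_between, 0.0, abs_tol=1e-300):
            return AnovaResult(0.0, df_b, df_w, 1.0, means, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, means, 0.0)

    F = (ss_between / df_b) / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, means, float(ms_w))


def snk_posthoc(samples: GroupSamples, alpha: float = 0.05) -> list[PairwiseComparison]:
    """Student-Newman-Keuls step-down comparisons over all group pairs.

    q = |mean_a - mean_b| / sqrt(MS_within / n_h), with n_h the harmonic
    mean of the two group sizes, referred to the Studentized range
    distribution at (r, df_within) where r is the number of ordered means
    the pair spans. Pairs inside a span already declared homogeneous are
    forced non-significant regardless of their own q.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    anova = one_way_anova(samples)
    groups = samples.groups

    # sort by mean, ties broken by label for determinism
    ordered = sorted(groups, key=lambda g: (anova.group_means[g], g))
    k = len(ordered)
    df_w = anova.df_within
    ms_w = anova.ms_within

    degenerate = ms_w == 0.0
    if degenerate:
        warnings.warn(
            f"{samples.outcome_name!r}: MS_within is 0; all pairs with unequal "
            "means are declared significant by convention"
        )

    ns_spans: list[tuple[int, int]] = []  # index intervals declared homogeneous
    comparisons: list[PairwiseComparison] = []
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            a, b = ordered[i], ordered[j]
            diff = anova.group_means[b] - anova.group_means[a]
            blocked = any(lo <= i and j <= hi for lo, hi in ns_spans)
            if degenerate:
                q = math.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                n_h = 2.0 / (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
                q = abs(diff) / math.sqrt(ms_w / n_h)
                p = float(stats.studentized_range.sf(q, r, df_w))
            significant = (not blocked) and p < alpha
            if not significant:
                ns_spans.append((i, j))
            comparisons.append(
                PairwiseComparison(
                    group_a=a,
                    group_b=b,
                    mean_diff=diff,
                    q_statistic=float(q),
                    span_r=r,
                    p=p,
                    significant=significant,
                    blocked=blocked,
                )
            )
    return comparisons


def compact_letter_display(comparisons: list[PairwiseComparison]) -> LetterDisplay:
    """Insert-and-absorb letter assignment from a pairwise significance relation.

    Letters are assigned in ascending-mean order starting at "a"; two groups
    share at least one letter exactly when their comparison was
    non-significant.
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    # recover ascending-mean order: group means are recoverable up to a
    # constant from the pairwise differences
    score: dict[str, float] = {}
    for c in comparisons:
        score.setdefault(c.group_a, 0.0)
        score.setdefault(c.group_b, 0.0)
        score[c.group_a] -= c.mean_diff
        score[c.group_b] += c.mean_diff
    order = sorted(score, key=lambda g: (score[g], g))
    rank = {g: i for i, g in enumerate(order)}

    expected = {frozenset((a, b)) for a in order for b in order if a < b}
    seen = {frozenset((c.group_a, c.group_b)) for c in comparisons}
    if expected != seen:
        raise ValueError("comparisons must cover every pair of groups exactly once")

    columns: list[set[str]] = [set(order)]
    sig_pairs = [
        (c.group_a, c.group_b) for c in comparisons if c.significant
    ]
    for a, b in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop duplicates and any column contained in another
        uniq: list[set[str]] = []
        for col in new_columns:
            if col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]

    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[idx]
    return LetterDisplay(letters=letters)


@dataclass(frozen=True)
class RegionScreen:
    """Per-region ANOVA results and letter codes across conditions."""

    results: dict[str, tuple[AnovaResult, LetterDisplay]]
    alpha: float
    conditions: tuple[str, ...]
    multiple_testing_corrected: bool = False  # per-outcome screens, uncorrected

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, (anova, cld) in self.results.items():
            row = {
                "outcome": region,
                "F": anova.F,
                "df1": anova.df_between,
                "df2": anova.df_within,
                "p": anova.p,
            }
            for cond in self.conditions:
                row[f"letters_{cond}"] = cld.letters.get(cond, "")
            rows.append(row)
        return pd.DataFrame(rows)


def screen_regions(study: StudyDataset, alpha: float = 0.05) -> RegionScreen:
    """ANOVA + SNK + letters for every region across the study's conditions.

    Regions whose omnibus ANOVA does not reach ``alpha`` get one shared
    letter and no post hoc. A region absent from some condition is skipped
    with a warning.
    """
    conditions = list(study.conditions)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to screen")
    results: dict[str, tuple[AnovaResult, LetterDisplay]] = {}
    for region in study.region_set:
        missing = [
            c for c, t in study.conditions.items() if region not in t.data.columns
        ]
        if missing:
            warnings.warn(f"region {region!r} missing in condition(s) {missing}; skipped")
            continue
        samples = GroupSamples(
            region,
            {c: study.conditions[c].data[region].to_numpy() for c in conditions},
        )
        anova = one_way_anova(samples)
        if anova.p < alpha:
            cld = compact_letter_display(snk_posthoc(samples, alpha=alpha))
        else:
            cld = LetterDisplay({c: "a" for c in conditions})
        results[region] = (anova, cld)
    return RegionScreen(results=results, alpha=alpha, conditions=tuple(conditions))
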