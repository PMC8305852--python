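"""Metabolite-table statistics: totals, fractions, folds, ANOVA with letters.

Operates on tidy concentration tables in two shapes:

* replicate level — columns ``line, replicate, compound, value``;
* summary level — columns ``line, compound, mean, sd`` (printed tables are
  mean +/- sd of n = 3 biological replicates).

Not-detected entries are NaN; they count as zero in totals (the printed
tables still sum over ND rows) but are excluded from ANOVA replicate vectors,
where a variance over ND would be meaningless.

Rounding is half away from zero, matching printed precision: 2 decimals for
umol-scale glucosinolates, 1 decimal for ug-scale hydrolysis products and
fold ratios.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away

TOTAL_COMPOUND = "Total"


def _summary_means(table: pd.DataFrame, line: str) -> pd.Series:
    """Per-compound mean for one line, from either table shape."""
    sub = table[table["line"] == line]
    if sub.empty:
        raise ValueError(f"unknown line {line!r}")
    if "mean" in table.columns:
        return sub.set_index("compound")["mean"]
    return sub.groupby("compound", sort=False)["value"].mean()


def total_concentration(table: pd.DataFrame, line: str, decimals: int = 2) -> float:
    """Sum of per-compound means for one line (ND counts as zero).

    Any printed ``Total`` row is excluded from the sum; negative
    concentrations are rejected.
    """
    means = _summary_means(table, line)
    means = means[means.index != TOTAL_COMPOUND]
    if (means.dropna() < 0).any():
        raise ValueError(f"negative concentration for line {line!r}")
    return round_half_away(float(means.fillna(0.0).sum()), decimals)


def component_fraction(table: pd.DataFrame, line: str, compound: str) -> int:
    """Compound share of the line's total, as a whole-number percentage."""
    means = _summary_means(table, line)
    total = float(means[means.index != TOTAL_COMPOUND].fillna(0.0).sum())
    if total <= 0:
        raise ValueError(f"line {line!r} has zero total; fraction undefined")
    value = means.get(compound)
    if value is None or pd.isna(value):
        value = 0.0
    return int(round_half_away(100.0 * float(value) / total, 0))


def fold_change(
    table: pd.DataFrame,
    line: str,
    control: str,
    compound: str | None = None,
    decimals: int = 1,
) -> float:
    """Ratio of a line over a control: totals by default, or one compound.

    Totals are computed from unrounded component sums; the result is rounded
    to ``decimals`` (printed fold convention: 1 decimal).
    """
    if compound is None:
        num_means = _summary_means(table, line)
        den_means = _summary_means(table, control)
        num = float(num_means[num_means.index != TOTAL_COMPOUND].fillna(0.0).sum())
        den = float(den_means[den_means.index != TOTAL_COMPOUND].fillna(0.0).sum())
    else:
        num = float(_summary_means(table, line).get(compound, np.nan))
        den = float(_summary_means(table, control).get(compound, np.nan))
        if np.isnan(num) or np.isnan(den):
            raise ValueError(f"compound {compound!r} missing for line or control")
    if den == 0:
        raise ValueError("control value is zero; fold change undefined")
    return round_half_away(num / den, decimals)


def screen_lines(
    table: pd.DataFrame, compound: str, threshold: float, direction: str = "<"
) -> set[str]:
    """Lines whose compound mean satisfies the inequality (ND counts as zero)."""
    ops = {
        "<": np.less, "<=": np.less_equal,
        ">": np.greater, ">=": np.greater_equal,
    }
    if direction not in ops:
        raise ValueError(f"direction must be one of {sorted(ops)}")
    passing: set[str] = set()
    for line in table["line"].unique():
        means = _summary_means(table, line)
        value = means.get(compound)
        if value is None:
            raise ValueError(f"compound {compound!r} missing for line {line!r}")
        value = 0.0 if pd.isna(value) else float(value)
        if ops[direction](value, threshold):
            passing.add(str(line))
    return passing


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA decomposition."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f_value: float
    p_value: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass
class GroupComparison:
    """ANOVA table plus post-hoc compact letter display.

    Levels sharing a letter are not significantly different at ``alpha``
    under the chosen post-hoc method.
    """

    levels: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    anova: AnovaResult
    letters: dict[str, str]
    method: str
    alpha: float
    summary_based: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "n": [self.ns[l] for l in self.levels],
                "mean": [self.means[l] for l in self.levels],
                "letters": [self.letters[l] for l in self.levels],
            }
        )


def _groups_from_input(
    data, n_summary: int
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, bool]:
    """Normalise input to (levels, ns, means, sds, summary_based)."""
    if isinstance(data, Mapping):
        levels = list(data)
        vectors = [np.asarray(data[l], dtype=float) for l in levels]
        vectors = [v[~np.isnan(v)] for v in vectors]
        for l, v in zip(levels, vectors):
            if len(v) < 2:
                raise ValueError(f"level {l!r} has fewer than 2 replicates")
        ns = np.array([len(v) for v in vectors])
        means = np.array([v.mean() for v in vectors])
        sds = np.array([v.std(ddof=1) for v in vectors])
        return levels, ns, means, sds, False
    if isinstance(data, pd.DataFrame):
        if {"mean", "sd"} <= set(data.columns):
            levels = [str(l) for l in data["line" if "line" in data.columns else "level"]]
            ns = (
                data["n"].to_numpy(dtype=int)
                if "n" in data.columns
                else np.full(len(levels), n_summary)
            )
            for l, n in zip(levels, ns):
                if n < 2:
                    raise ValueError(f"level {l!r} has fewer than 2 replicates")
            return levels, ns, data["mean"].to_numpy(float), data["sd"].to_numpy(float), True
        level_col = "line" if "line" in data.columns else "level"
        groups = {
            str(l): sub["value"].to_numpy(float) for l, sub in data.groupby(level_col, sort=False)
        }
        return _groups_from_input(groups, n_summary)
    raise TypeError("data must be a mapping level -> values or a DataFrame")


def anova_oneway_summary(ns: np.ndarray, means: np.ndarray, sds: np.ndarray) -> AnovaResult:
    """One-way ANOVA reconstructed from per-level (n, mean, sd)."""
    if len(ns) < 2:
        raise ValueError("need at least 2 levels")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = len(ns) - 1
    df_within = n_total - len(ns)
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w == 0.0:
        f = 0.0 if ms_b == 0.0 else np.inf
    else:
        f = ms_b / ms_w
    p = float(stats.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    return AnovaResult(ss_between, ss_within, df_between, df_within, float(f), p)


@lru_cache(maxsize=512)
def _q_crit(p: float, k: int, df: int) -> float:
    """Cached studentized-range quantile (the ppf is expensive)."""
    return float(stats.studentized_range.ppf(p, k, df))


def _pairwise_different(
    ns: np.ndarray,
    means: np.ndarray,
    ms_within: float,
    df_within: int,
    alpha: float,
    method: str,
) -> np.ndarray:
    """Boolean matrix: True where two levels differ significantly.

    ``tukey`` uses the single studentized-range critical value of Tukey's HSD
    (Tukey-Kramer standard error for unequal n); ``duncan`` uses the multiple
    range test, where the critical value grows with the number of ordered
    means spanned and the protection level is 1 - (1 - alpha)^(r-1).
    """
    k = len(means)
    diff = np.zeros((k, k), dtype=bool)
    if ms_within == 0.0:
        for i in range(k):
            for j in range(i + 1, k):
                diff[i, j] = diff[j, i] = means[i] != means[j]
        return diff
    order = np.argsort(-means)  # descending
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            span = abs(int(rank[i]) - int(rank[j])) + 1
            if method == "tukey":
                q_crit = _q_crit(1.0 - alpha, k, df_within)
            elif method == "duncan":
                alpha_r = 1.0 - (1.0 - alpha) ** (span - 1)
                q_crit = _q_crit(1.0 - alpha_r, span, df_within)
            else:
                raise ValueError(f"unknown post-hoc method {method!r}")
            diff[i, j] = diff[j, i] = abs(means[i] - means[j]) > q_crit * se
    if method == "duncan":
        # protection rule: a pair inside a non-significant span is non-significant
        for a in range(k):
            for b in range(a + 1, k):
                ia, ib = order[a], order[b]
                if not diff[ia, ib]:
                    for x in range(a, b + 1):
                        for y in range(x + 1, b + 1):
                            diff[order[x], order[y]] = diff[order[y], order[x]] = False
    return diff


def compact_letter_display(
    levels: Sequence[str], means: np.ndarray, diff: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Letters are assigned from the highest-mean level downward ('a' first);
    every letter marks a maximal set of mutually non-different levels.
    """
    k = len(levels)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not diff[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.extend(({x for x in col if x != i}, {x for x in col if x != j}))
                # absorb columns contained in another
                columns = [
                    c
                    for c in columns
                    if not any(c < other for other in columns)
                ]
    # dedupe, then order by the best (highest) mean each column contains
    unique_cols = []
    for c in columns:
        if c and c not in unique_cols:
            unique_cols.append(c)
    unique_cols.sort(key=lambda c: (-max(means[i] for i in c), -len(c)))
    letters: dict[int, str] = {i: "" for i in range(k)}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(alphabet, unique_cols):
        for i in sorted(col):
            letters[i] += letter
    return {levels[i]: letters[i] for i in range(k)}


def anova_with_letters(
    data,
    alpha: float = 0.05,
    method: str = "tukey",
    n_summary: int = 3,
) -> GroupComparison:
    """One-way ANOVA plus post-hoc compact letter display.

    ``data`` may be a mapping level -> replicate values, a replicate-level
    DataFrame (``line``/``level`` and ``value`` columns), or a summary
    DataFrame (``mean``/``sd`` and optional ``n``; ``n_summary`` fills in a
    missing replicate count). Summary input is flagged in the result.
    """
    levels, ns, means, sds, summary_based = _groups_from_input(data, n_summary)
    anova = anova_oneway_summary(ns, means, sds)
    diff = _pairwise_different(ns, means, anova.ms_within, anova.df_within, alpha, method)
    letters = compact_letter_display(levels, means, diff)
    return GroupComparison(
        levels=levels,
        means={l: float(m) for l, m in zip(levels, means)},
        ns={l: int(n) for l, n in zip(levels, ns)},
        anova=anova,
        letters=letters,
        method=method,
        alpha=alpha,
        summary_based=summary_based,
    )
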