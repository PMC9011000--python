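"""Group-wise trait statistics and expression–trait correlation.

Duncan's multiple range test after one-way ANOVA: sorted group means are
compared with least significant ranges built from studentized-range
quantiles at the protection level 1 − (1 − α)^(p−1) for a span of p means;
unequal group sizes use the harmonic mean of the pair's sizes (Kramer
adjustment).  Quantiles are computed numerically from the studentized-range
distribution, not from printed tables.  Decisions are summarized as a
compact letter display via insert-and-absorb.

Expression–trait association is the two-tailed Pearson test (t transform
with n − 2 df) with the conventional star annotation (* p<0.05, ** p<0.01,
*** p<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


class DegenerateDataError(ValueError):
    """Zero within-group variance with unequal means: the range test has no
    error scale to compare against."""


def dressing_percentage(hot_carcass: float, live_weight: float) -> float:
    """Hot carcass weight as a percentage of live weight."""
    if live_weight <= 0:
        raise InputError("live weight must be positive")
    return hot_carcass / live_weight * 100.0


# ------------------------------------------------------------ Duncan MRT


@lru_cache(maxsize=4096)
def _q_crit(alpha_p: float, span: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha_p, span, df))


@dataclass
class DuncanResult:
    trait: str
    means: pd.Series  # group → mean, sorted descending
    mse: float
    error_df: int
    alpha: float
    decisions: dict[frozenset, bool] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)

    def different(self, g1: str, g2: str) -> bool:
        return self.decisions[frozenset((g1, g2))]


def duncan_mrt(table: pd.DataFrame, trait: str, alpha: float = 0.05,
               group_col: str = "group") -> DuncanResult:
    """Duncan's multiple range test for one trait of a sample×trait table.

    ``table`` must carry a group column and the trait column.  Groups need
    ≥ 2 observations.  A pair of means differs when its gap exceeds the
    least significant range for its span and no enclosing span has already
    been declared homogeneous (the standard step-down protection).
    """
    if trait not in table.columns:
        raise InputError(f"trait {trait!r} not in table")
    values = table[[group_col, trait]].dropna()
    groups = values.groupby(group_col)[trait]
    sizes = groups.size()
    if len(sizes) < 2:
        raise InputError("need at least 2 groups")
    if (sizes < 2).any():
        raise InputError("every group needs at least 2 observations")
    means = groups.mean().sort_values(ascending=False)
    names = list(means.index)
    g = len(names)
    n_total = int(sizes.sum())
    df = n_total - g
    sse = float(((values[trait] - values[group_col].map(groups.mean())) ** 2).sum())
    mse = sse / df

    decisions: dict[frozenset, bool] = {}
    if mse == 0.0:
        if np.allclose(means.values, means.values[0]):
            for i in range(g):
                for j in range(i + 1, g):
                    decisions[frozenset((names[i], names[j]))] = False
            letters = {name: "a" for name in names}
            return DuncanResult(trait, means, mse, df, alpha, decisions, letters)
        raise DegenerateDataError(
            f"zero within-group variance with unequal means for {trait!r}"
        )

    # step-down over spans: outer nonsignificant spans block inner pairs
    blocked: list[tuple[int, int]] = []
    for span in range(g, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        for i in range(0, g - span + 1):
            j = i + span - 1
            pair = frozenset((names[i], names[j]))
            if any(bi <= i and j <= bj for bi, bj in blocked):
                decisions[pair] = False
                blocked.append((i, j))
                continue
            n_h = 2.0 / (1.0 / sizes[names[i]] + 1.0 / sizes[names[j]])
            lsr = _q_crit(alpha_p, span, df) * np.sqrt(mse / n_h)
            diff = means.iloc[i] - means.iloc[j]
            if diff > lsr:
                decisions[pair] = True
            else:
                decisions[pair] = False
                blocked.append((i, j))

    letters = compact_letter_display(names, decisions)
    return DuncanResult(trait, means, mse, df, alpha, decisions, letters)


def compact_letter_display(
    ordered_groups: list[str], decisions: dict[frozenset, bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Start from one column holding every group; for each significantly
    different pair present in a column, split the column into two (one
    without each member); absorb columns contained in another.  Letters are
    assigned to surviving columns in order of their best-ranked member.
    """
    columns: list[set[str]] = [set(ordered_groups)]
    sig_pairs = [tuple(p) for p, d in sorted(
        decisions.items(), key=lambda kv: sorted(kv[0])) if d]
    for g1, g2 in sig_pairs:
        new_columns = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in columns:
                continue
            columns.append(col)
    rank = {name: i for i, name in enumerate(ordered_groups)}
    columns.sort(key=lambda col: min(rank[m] for m in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in ordered_groups}
    for idx, col in enumerate(columns):
        for name in col:
            letters[name] += alphabet[idx % len(alphabet)]
    return letters


def letters_table(results: list[DuncanResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for grp in r.means.index:
            rows.append({"trait": r.trait, "group": grp,
                         "mean": r.means[grp], "letters": r.letters[grp]})
    return pd.DataFrame(rows, columns=["trait", "group", "mean", "letters"])


# ------------------------------------------------- expression vs. traits


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class TraitCorrelation:
    circ_id: str
    trait: str
    r: float
    p: float
    n: int
    stars: str


def trait_circ_correlation(
    expr: ExpressionMatrix, traits: pd.DataFrame, trait_names=None,
    group_col: str = "group",
) -> list[TraitCorrelation]:
    """Pearson correlation of each circRNA's expression against each trait,
    two-tailed p from the t transform, starred per the usual convention.
    Zero-variance vectors are reported as missing (NaN) with a log entry."""
    shared = [s for s in expr.samples if s in traits.index]
    if len(shared) < 3:
        raise InputError("need at least 3 shared samples")
    if trait_names is None:
        trait_names = [c for c in traits.columns if c != group_col]
    out = []
    n = len(shared)
    tmat = traits.loc[shared]
    for circ in expr.features:
        x = expr.data.loc[circ, shared].to_numpy(dtype=float)
        for trait in trait_names:
            y = tmat[trait].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                logger.info("zero-variance vector for (%s, %s)", circ, trait)
                out.append(TraitCorrelation(circ, trait, float("nan"),
                                            float("nan"), n, ""))
                continue
            r, p = stats.pearsonr(x, y)
            out.append(TraitCorrelation(circ, trait, float(r), float(p), n,
                                        stars(float(p))))
    return out


def correlation_table(correlations: list[TraitCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in correlations],
            "trait": [c.trait for c in correlations],
            "r": [c.r for c in correlations],
            "p": [c.p for c in correlations],
            "n": [c.n for c in correlations],
            "stars": [c.stars for c in correlations],
        }
    )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
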