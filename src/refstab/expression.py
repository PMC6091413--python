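"""Target-gene expression via 2^-ddCT and group comparison.

Validates a chosen reference-gene set by normalizing a target gene against
it: ``dCT_s = CT_target,s - mean(CT_refs,s)`` (the arithmetic mean of
reference CTs equals the geometric mean of their quantities at E = 2),
``ddCT_s = dCT_s - mean(dCT over calibrator samples)``, expression
``2**-ddCT``.  Group differences are tested with one-way ANOVA followed by
Tukey's HSD, summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_model import CTTable


@dataclass
class ExpressionResult:
    target: str
    refs: list[str]
    calibrator: str
    expression: pd.Series        # per sample, positive
    group_stats: pd.DataFrame    # per level: mean, sd, n

    @property
    def normalizer_label(self) -> str:
        return "+".join(self.refs)


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    alpha: float
    letters: dict[str, str]           # group -> letters, e.g. "AB"
    pairwise_p: pd.DataFrame          # symmetric matrix of Tukey p-values


def ddct_expression(
    table: CTTable,
    target: str,
    refs: Sequence[str],
    calibrator: str | None = None,
) -> ExpressionResult:
    """Relative expression of ``target`` normalized to ``refs`` via 2^-ddCT.

    ``calibrator`` names the condition level whose mean dCT is the baseline
    (its group-mean expression is 1 by construction); defaults to the first
    level in sorted sample order.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("need at least one reference gene")
    if target in refs:
        raise ValueError(f"target {target!r} cannot be its own reference")
    m = table.matrix
    missing = [g for g in [target] + refs if g not in m.index]
    if missing:
        raise KeyError(f"genes absent from table: {missing}")

    levels = table.levels().loc[m.columns]
    if calibrator is None:
        calibrator = levels.iloc[0]
    if calibrator not in set(levels):
        raise ValueError(f"calibrator {calibrator!r} is not a level of this table")

    dct = m.loc[target] - m.loc[refs].mean(axis=0)
    baseline = dct[levels == calibrator].mean()
    expr = np.power(2.0, -(dct - baseline))
    expr.name = "expression"

    stats_df = (
        pd.DataFrame({"expression": expr, "level": levels})
        .groupby("level", sort=False)["expression"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
    )
    return ExpressionResult(
        target=target,
        refs=refs,
        calibrator=calibrator,
        expression=expr,
        group_stats=stats_df,
    )


def compare_normalizers(
    table: CTTable,
    target: str,
    normalizers: Sequence[Sequence[str]],
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Fold ratios of group-mean expression between normalizer choices.

    For every condition level and every ordered pair of normalizers (a, b),
    the ratio of the group-mean expressions ``mean_a / mean_b``.  Ratios far
    from 1 flag normalizers that disagree — the signature of an unstable
    reference gene.
    """
    normalizers = [list(n) for n in normalizers]
    if len(normalizers) < 2:
        raise ValueError("need at least 2 normalizers to compare")
    results = [
        ddct_expression(table, target, refs, calibrator) for refs in normalizers
    ]
    rows = []
    for (ia, ra), (ib, rb) in itertools.permutations(enumerate(results), 2):
        for level in ra.group_stats.index:
            rows.append(
                {
                    "level": level,
                    "normalizer_a": ra.normalizer_label,
                    "normalizer_b": rb.normalizer_label,
                    "ratio": ra.group_stats.loc[level, "mean"]
                    / rb.group_stats.loc[level, "mean"],
                }
            )
    return pd.DataFrame(rows)


def one_way_anova(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Classical one-way ANOVA; needs >= 2 groups with >= 2 values each."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups, dtype=object))
    if len(s) != len(g):
        raise ValueError("values and groups differ in length")
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError(
            f"every group needs >= 2 values; too small: {list(counts[counts < 2].index)}"
        )
    arrays = [s[g == name].to_numpy() for name in counts.index]
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # all groups identical and constant
        return 0.0, 1.0
    return float(f), float(p)


def _compact_letters(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts with one letter covering all groups; for each significantly
    different pair present in a shared letter set, the set is split in two
    (one side dropping each member), and letter sets contained in another
    are absorbed.  The result: two groups share a letter iff they are not
    significantly different-connected by the input pairs.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb subsets
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns if col is not other):
                continue
            if col in columns:
                continue
            columns.append(col)
    # stable letter assignment: order columns by their best-placed member
    pos = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else len(groups))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        if i >= len(alphabet):
            raise ValueError("more letter groups than letters")
        for g in col:
            letters[g] += alphabet[i]
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_letters(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Tukey HSD after one-way ANOVA, reported as a compact letter display.

    Groups sharing any letter do not differ at ``alpha``; any two groups
    whose Tukey p-value is below ``alpha`` share no letter.
    """
    f, p = one_way_anova(values, groups)
    s = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    group_names = list(pd.unique(g))

    tk = pairwise_tukeyhsd(s, g, alpha=alpha)
    pmat = pd.DataFrame(1.0, index=group_names, columns=group_names, dtype=float)
    for (a, b), pv in zip(
        itertools.combinations(sorted(group_names), 2), tk.pvalues
    ):
        pmat.loc[a, b] = pmat.loc[b, a] = float(pv)
    np.fill_diagonal(pmat.values, 1.0)

    significant = {
        (a, b)
        for a, b in itertools.combinations(group_names, 2)
        if pmat.loc[a, b] < alpha
    }
    significant = {tuple(sorted(pair)) for pair in significant}
    letters = _compact_letters(group_names, significant)
    return GroupComparison(
        f_statistic=f, p_value=p, alpha=alpha, letters=letters, pairwise_p=pmat
    )
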