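"""How many reference genes to use: geNorm pairwise variation and NF checks.

Given genes ordered best-first by geNorm stability, the normalization factor
NF_n of a sample is the geometric mean of the quantities of the n most stable
genes.  The pairwise variation ``V_n = SD over samples of log2(NF_n / NF_n+1)``
measures how much adding the (n+1)-th gene changes normalization; the first
``V_n`` below the 0.15 cutoff recommends n genes, and when no V clears the
cutoff the smallest V is taken instead.  A Pearson correlation between NF_3
and NF at the chosen count quantifies whether three genes already suffice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import QuantityMatrix

DEFAULT_CUTOFF = 0.15


def normalization_factor(q: QuantityMatrix, genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the quantities of ``genes`` (>= 2 of them)."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a normalization factor needs at least 2 genes")
    missing = [g for g in genes if g not in q.q.index]
    if missing:
        raise KeyError(f"genes not in quantity matrix: {missing}")
    log_q = np.log(q.q.loc[genes])
    return pd.Series(np.exp(log_q.mean(axis=0)), index=q.q.columns, name="nf")


def pairwise_variations(
    q: QuantityMatrix, ordered_genes: Sequence[str]
) -> pd.Series:
    """V_n for n = 2 .. n_genes - 1, given the geNorm best-first gene order."""
    ordered = list(ordered_genes)
    n_genes = len(ordered)
    if n_genes < 3:
        raise ValueError("pairwise variation needs at least 3 genes")
    out = {}
    for n in range(2, n_genes):
        nf_n = np.log2(normalization_factor(q, ordered[:n]))
        nf_n1 = np.log2(normalization_factor(q, ordered[: n + 1]))
        out[n] = float((nf_n - nf_n1).std(ddof=1))
    return pd.Series(out, name="V")


def choose_gene_count(
    v: pd.Series | Sequence[float], cutoff: float = DEFAULT_CUTOFF
) -> tuple[int, str]:
    """Pick the reference-gene count from the V list.

    Returns ``(chosen_n, rule)`` where rule is ``"below_cutoff"`` (smallest n
    with V_n < cutoff) or ``"lowest_V"`` (no V clears the cutoff; the smallest
    V wins, ties to the smallest n).
    """
    if isinstance(v, pd.Series):
        series = v.astype(float)
    else:
        series = pd.Series(
            np.asarray(v, dtype=float), index=range(2, 2 + len(v))
        )
    if series.empty:
        raise ValueError("empty V list")
    below = series[series < cutoff]
    if not below.empty:
        return int(below.index.min()), "below_cutoff"
    lowest = series.min()
    return int(series[series == lowest].index.min()), "lowest_V"


def nf_correlation(
    nf_a: pd.Series, nf_b: pd.Series, scale: str = "log"
) -> float | None:
    """Pearson r between two NF vectors, on log2 scale by default.

    NFs are geometric-mean quantities, so the log scale is the natural one;
    ``scale="linear"`` is available for comparison.  Returns None when either
    vector has zero variance (r undefined).
    """
    a = np.asarray(nf_a, dtype=float)
    b = np.asarray(nf_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("NF vectors must have equal length >= 3")
    if scale == "log":
        a, b = np.log2(a), np.log2(b)
    elif scale != "linear":
        raise ValueError("scale must be 'log' or 'linear'")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r, _ = stats.pearsonr(a, b)
    return float(r)


@dataclass
class GeneCountResult:
    """Everything the gene-count decision produced, for one condition set."""

    ordered_genes: list[str]
    nf: pd.DataFrame            # sample x n (columns n = 2 .. n_genes)
    v: pd.Series                # V_n, index n = 2 .. n_genes - 1
    cutoff: float
    chosen_n: int
    rule_used: str
    nf_correlation_r: float | None       # log2 scale
    nf_correlation_r_linear: float | None

    @property
    def recommended_genes(self) -> list[str]:
        return self.ordered_genes[: self.chosen_n]


def gene_count_analysis(
    q: QuantityMatrix,
    ordered_genes: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> GeneCountResult:
    """Full gene-count workflow: NF ladder, V list, count choice, NF_3 check."""
    ordered = list(ordered_genes)
    v = pairwise_variations(q, ordered)
    chosen_n, rule = choose_gene_count(v, cutoff)
    nf = pd.DataFrame(
        {n: normalization_factor(q, ordered[:n]) for n in range(2, len(ordered) + 1)}
    )
    r = r_lin = None
    if len(ordered) >= 3:
        nf3 = nf[3]
        nf_chosen = nf[chosen_n]
        r = nf_correlation(nf3, nf_chosen, scale="log")
        r_lin = nf_correlation(nf3, nf_chosen, scale="linear")
    return GeneCountResult(
        ordered_genes=ordered,
        nf=nf,
        v=v,
        cutoff=cutoff,
        chosen_n=chosen_n,
        rule_used=rule,
        nf_correlation_r=r,
        nf_correlation_r_linear=r_lin,
    )
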