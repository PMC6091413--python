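"""The four reference-gene stability statistics.

Each method scores every candidate gene on one condition set; lower is more
stable.  All four are implemented from their published definitions:

* geNorm: mean pairwise SD of log quantity ratios (M value), with stepwise
  exclusion of the least stable gene.
* NormFinder: model-based decomposition of per-gene variation into intragroup
  variance and (shrunk) intergroup deviation.
* BestKeeper: descriptive dispersion of raw CT (SD as mean absolute
  deviation) plus correlation with the per-sample geometric-mean CT index.
* Comparative dCT: mean SD of a gene's CT differences to every other gene.

Ranks use the min-tie ("1, 1, 3") competition convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CTTable, QuantityMatrix

METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


def assign_ranks(values: pd.Series, ascending: bool = True) -> pd.Series:
    """Min-tie competition ranks (ties share the smallest rank; next rank skips).

    Ascending by default: the smallest value — the most stable gene — gets
    rank 1, matching how stability tables are printed.
    """
    v = pd.Series(values, dtype=float)
    if not np.isfinite(v.to_numpy()).all():
        raise ValueError("ranks require finite values")
    arr = v.to_numpy() if ascending else -v.to_numpy()
    ranks = stats.rankdata(arr, method="min")
    return pd.Series(ranks.astype(int), index=v.index, name="rank")


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks for one method on one condition set."""

    method: str
    stability: pd.Series
    ranks: pd.Series
    detail: object | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.stability.index, "method": self.method,
             "stability": self.stability.values, "rank": self.ranks.values}
        )


# -- geNorm ------------------------------------------------------------------


@dataclass
class GenormDetail:
    full_panel_m: pd.Series
    exclusion_order: list[str]
    m_at_step: list[float]
    final_pair: tuple[str, str]
    stability_order: list[str]  # best first


def _pairwise_v(log_q: pd.DataFrame) -> pd.DataFrame:
    """V[j, k] = SD over samples of log2(q_j / q_k), n-1 divisor."""
    a = log_q.to_numpy()
    diff = a[:, None, :] - a[None, :, :]
    v = diff.std(axis=2, ddof=1)
    return pd.DataFrame(v, index=log_q.index, columns=log_q.index)


def _m_values(log_q: pd.DataFrame) -> pd.Series:
    v = _pairwise_v(log_q)
    n = len(v)
    m = (v.sum(axis=1)) / (n - 1)  # diagonal is zero
    return m


def genorm(q: QuantityMatrix) -> StabilityResult:
    """geNorm expression-stability measure M with stepwise exclusion.

    The reported per-gene stability is its M value at the step it was
    excluded; the final two genes cannot be distinguished, share the
    last-step M and both rank 1.  Ties for the current worst M are broken by
    excluding the lexicographically last gene symbol (deterministic).
    """
    if len(q.gene_symbols) < 3:
        raise ValueError("geNorm requires at least 3 genes")
    if len(q.sample_ids) < 2:
        raise ValueError("geNorm requires at least 2 samples")
    log_q = q.log2()
    full_m = _m_values(log_q)

    remaining = list(log_q.index)
    stability: dict[str, float] = {}
    exclusion_order: list[str] = []
    m_at_step: list[float] = []
    while len(remaining) > 2:
        m = _m_values(log_q.loc[remaining])
        worst_val = m.max()
        worst = max(g for g in remaining if m[g] == worst_val)
        stability[worst] = float(m[worst])
        exclusion_order.append(worst)
        m_at_step.append(float(m[worst]))
        remaining.remove(worst)

    pair_m = float(_m_values(log_q.loc[remaining]).iloc[0])
    for g in remaining:
        stability[g] = pair_m

    stab = pd.Series(stability).reindex(log_q.index)
    ranks = assign_ranks(stab)
    order = sorted(remaining) + list(reversed(exclusion_order))
    detail = GenormDetail(
        full_panel_m=full_m,
        exclusion_order=exclusion_order,
        m_at_step=m_at_step,
        final_pair=tuple(sorted(remaining)),
        stability_order=order,
    )
    return StabilityResult("genorm", stab, ranks, detail)


# -- NormFinder --------------------------------------------------------------


@dataclass
class NormfinderDetail:
    groups: pd.Series | None
    intergroup_deviation: pd.DataFrame | None  # d-hat, gene x group
    shrunk_deviation: pd.DataFrame | None      # d-tilde, gene x group
    intragroup_variance: pd.DataFrame          # sigma-hat^2, gene x group
    intergroup_variance: float | None          # gamma-hat^2


def _single_group_variances(z: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variances from sample-centred log expression.

    ``z`` is gene x sample, already centred across genes within each sample.
    Centring makes the naive per-gene variance s2_i absorb a share of every
    other gene's variance; the corrector
    ``max(0, (s2_i - mean(s2)/(k-1)) * k/(k-2))`` undoes that on average.
    """
    k = z.shape[0]
    if k < 3:
        raise ValueError("NormFinder requires at least 3 genes")
    s2 = z.var(axis=1, ddof=1)
    corrected = (s2 - s2.mean() / (k - 1)) * k / (k - 2)
    return np.maximum(corrected, 0.0)


def normfinder(
    y: pd.DataFrame, groups: pd.Series | Sequence[str] | None = None
) -> StabilityResult:
    """NormFinder model-based stability on log2 expression.

    Parameters
    ----------
    y
        Gene x sample log2 quantities (equivalently ``(CTmin - CT) * log2(E)``).
    groups
        Per-sample group labels (condition levels).  With no groups — or a
        single group — the stability is the bias-corrected intragroup SD.
        With G >= 2 groups (each of size >= 2), the stability combines the
        shrunk intergroup deviation ``|d~_ig|`` with the sampling noise term,
        averaged over groups.
    """
    y = y.astype(float)
    k = y.shape[0]
    if k < 3:
        raise ValueError("NormFinder requires at least 3 genes")

    z = y - y.mean(axis=0)  # centre across genes within each sample

    if groups is not None:
        groups = pd.Series(np.asarray(groups, dtype=object), index=y.columns)
        n_groups = groups.nunique()
    else:
        n_groups = 1

    if n_groups <= 1:
        sigma2 = _single_group_variances(z.to_numpy())
        stab = pd.Series(np.sqrt(sigma2), index=y.index)
        detail = NormfinderDetail(
            groups=None,
            intergroup_deviation=None,
            shrunk_deviation=None,
            intragroup_variance=pd.DataFrame({"all": sigma2}, index=y.index),
            intergroup_variance=None,
        )
        return StabilityResult("normfinder", stab, assign_ranks(stab), detail)

    group_names = list(pd.unique(groups))
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(
            f"NormFinder groups need >= 2 samples; too small: {list(small.index)}"
        )

    G = len(group_names)
    n_g = np.array([sizes[g] for g in group_names], dtype=float)
    zbar_ig = np.column_stack(
        [z.loc[:, groups[groups == g].index].mean(axis=1) for g in group_names]
    )  # gene x group
    # grand mean weighted by group sizes equals the mean over all samples
    zbar_i = z.mean(axis=1).to_numpy()
    d_hat = zbar_ig - zbar_i[:, None]

    sigma2_ig = np.column_stack(
        [
            _single_group_variances(z.loc[:, groups[groups == g].index].to_numpy())
            for g in group_names
        ]
    )

    gamma2 = max(
        0.0,
        (d_hat**2).sum() / ((k - 1) * (G - 1)) - (sigma2_ig / n_g[None, :]).mean(),
    )
    noise = sigma2_ig / n_g[None, :]
    shrink = gamma2 / (gamma2 + noise) if gamma2 > 0 else np.zeros_like(noise)
    d_tilde = d_hat * shrink
    rho = (np.abs(d_tilde) + np.sqrt(noise * shrink)).mean(axis=1)

    stab = pd.Series(rho, index=y.index)
    detail = NormfinderDetail(
        groups=groups,
        intergroup_deviation=pd.DataFrame(d_hat, index=y.index, columns=group_names),
        shrunk_deviation=pd.DataFrame(d_tilde, index=y.index, columns=group_names),
        intragroup_variance=pd.DataFrame(
            sigma2_ig, index=y.index, columns=group_names
        ),
        intergroup_variance=float(gamma2),
    )
    return StabilityResult("normfinder", stab, assign_ranks(stab), detail)


# -- BestKeeper --------------------------------------------------------------


@dataclass
class BestkeeperDetail:
    descriptives: pd.DataFrame  # per gene: geo_mean, mean, min, max, sd, cv_pct
    index: pd.Series            # per-sample BestKeeper index (geo mean CT)
    correlation: pd.DataFrame   # per gene: r, p versus the index


def bestkeeper(table: CTTable, sd: str = "mad") -> StabilityResult:
    """BestKeeper descriptive stability on raw CT.

    The stability value is the "SD" of the original tool: the mean absolute
    deviation of CT from its arithmetic mean (``sd="mad"``); ``sd="classic"``
    switches to the n-1 standard deviation.  The detail block carries the
    per-sample BestKeeper index (geometric mean CT over genes) and each
    gene's Pearson correlation with it.
    """
    m = table.matrix
    if m.shape[0] < 2:
        raise ValueError("BestKeeper requires at least 2 genes")
    if m.shape[1] < 3:
        raise ValueError("BestKeeper requires at least 3 samples")
    if sd not in ("mad", "classic"):
        raise ValueError("sd must be 'mad' or 'classic'")

    mean = m.mean(axis=1)
    if sd == "mad":
        spread = (m.sub(mean, axis=0)).abs().mean(axis=1)
    else:
        spread = m.std(axis=1, ddof=1)
    geo_mean = np.exp(np.log(m).mean(axis=1))
    desc = pd.DataFrame(
        {
            "geo_mean": geo_mean,
            "mean": mean,
            "min": m.min(axis=1),
            "max": m.max(axis=1),
            "sd": spread,
            "cv_pct": spread / mean * 100.0,
        }
    )
    index = pd.Series(np.exp(np.log(m).mean(axis=0)), index=m.columns, name="index")
    corr = {}
    for g in m.index:
        x = m.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(index.to_numpy()) == 0:
            corr[g] = (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(x, index.to_numpy())
            corr[g] = (r, p)
    corr = pd.DataFrame(corr, index=["r", "p"]).T

    stab = desc["sd"].copy()
    detail = BestkeeperDetail(descriptives=desc, index=index, correlation=corr)
    return StabilityResult("bestkeeper", stab, assign_ranks(stab), detail)


# -- comparative dCT ---------------------------------------------------------


@dataclass
class DeltaCtDetail:
    pairwise_sd: pd.DataFrame  # SD over samples of CT_i - CT_j


def delta_ct(table: CTTable) -> StabilityResult:
    """Comparative dCT stability: mean SD of a gene's CT differences.

    For every gene pair (i, j) the SD over samples of ``CT_i - CT_j``
    (n-1 divisor); a gene's stability is the mean of its off-diagonal row.
    Operates on raw CT by definition — no efficiency correction.
    """
    m = table.matrix
    if m.shape[0] < 2:
        raise ValueError("comparative dCT requires at least 2 genes")
    if m.shape[1] < 2:
        raise ValueError("comparative dCT requires at least 2 samples")
    a = m.to_numpy()
    diff = a[:, None, :] - a[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    pair = pd.DataFrame(sd, index=m.index, columns=m.index)
    stab = pair.sum(axis=1) / (len(pair) - 1)
    detail = DeltaCtDetail(pairwise_sd=pair)
    return StabilityResult("deltact", stab, assign_ranks(stab), detail)


# -- orchestration helper ----------------------------------------------------


def run_all_methods(
    table: CTTable,
    q: QuantityMatrix | None = None,
    methods: Sequence[str] = METHODS,
    normfinder_groups: pd.Series | None | str = "auto",
    bestkeeper_sd: str = "mad",
) -> dict[str, StabilityResult]:
    """Run the requested stability methods on one collapsed condition set.

    ``normfinder_groups="auto"`` uses condition levels as groups when every
    level has at least 2 samples (and there are >= 2 levels), else falls back
    to single-group mode.
    """
    from .data_model import ct_to_quantity

    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if q is None:
        q = ct_to_quantity(table)

    results: dict[str, StabilityResult] = {}
    for meth in methods:
        if meth == "genorm":
            results[meth] = genorm(q)
        elif meth == "normfinder":
            groups = normfinder_groups
            if isinstance(groups, str) and groups == "auto":
                levels = table.levels(qualified=True)
                counts = levels.value_counts()
                groups = levels if (len(counts) >= 2 and counts.min() >= 2) else None
            y = q.log2().sort_index(axis=1)
            results[meth] = normfinder(
                y, groups.loc[y.columns] if groups is not None else None
            )
        elif meth == "bestkeeper":
            results[meth] = bestkeeper(table, sd=bestkeeper_sd)
        elif meth == "deltact":
            results[meth] = delta_ct(table)
    return results
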