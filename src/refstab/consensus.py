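"""Geometric-mean consensus of per-method stability rankings.

The comprehensive ranking integrates the four per-method rankings the way
the RefFinder tool does: each gene's consensus score is the geometric mean
of its per-method ranks, and genes sort ascending by that score (lower =
more stable).  Ties are broken by mean rank, then gene symbol, so the final
ordering is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConsensusResult:
    ranks: pd.DataFrame      # gene x method integer ranks
    geomean: pd.Series       # per-gene geometric mean rank
    ordering: list[str]      # best first
    final_rank: pd.Series    # 1..n following `ordering`
    top3: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out.columns = [f"rank_{m}" for m in out.columns]
        out["geomean"] = self.geomean
        out["final_rank"] = self.final_rank
        return out.loc[self.ordering].reset_index(names="gene")


def reffinder_consensus(ranks: pd.DataFrame) -> ConsensusResult:
    """Consensus ranking from a gene x method table of integer ranks.

    Every method must rank every gene and at least two methods are required
    — a "consensus" of one ranking would be a relabelling.
    """
    if ranks.shape[1] < 2:
        raise ValueError("consensus needs ranks from at least 2 methods")
    if ranks.isna().any().any():
        gene = ranks.index[ranks.isna().any(axis=1)][0]
        method = ranks.columns[ranks.isna().any(axis=0)][0]
        raise ValueError(f"gene {gene!r} has no rank for method {method!r}")
    r = ranks.astype(float)
    if (r < 1).any().any():
        raise ValueError("ranks must be >= 1")

    geomean = pd.Series(
        np.exp(np.log(r).mean(axis=1)), index=r.index, name="geomean"
    )
    mean_rank = r.mean(axis=1)
    order_key = pd.DataFrame(
        {"gm": geomean, "mean": mean_rank, "symbol": r.index.astype(str)}
    )
    ordering = list(order_key.sort_values(["gm", "mean", "symbol"]).index)
    final_rank = pd.Series(
        {g: i + 1 for i, g in enumerate(ordering)}, name="final_rank"
    ).reindex(r.index)
    return ConsensusResult(
        ranks=ranks.astype(int),
        geomean=geomean,
        ordering=ordering,
        final_rank=final_rank,
        top3=ordering[:3],
    )


def consensus_from_results(results: dict[str, "object"]) -> ConsensusResult:
    """Build the consensus from ``{method: StabilityResult}`` as produced by
    :func:`refstab.stability.run_all_methods`."""
    ranks = pd.DataFrame({m: res.ranks for m, res in results.items()})
    return reffinder_consensus(ranks)
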