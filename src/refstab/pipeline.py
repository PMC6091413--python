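"""End-to-end orchestration: per-condition-set stability, consensus,
gene-count and optional target-gene validation, plus the report bundle.

Pooled sets (``all_biotic``, ``all_abiotic``, ``all_samples``) are unions of
their member sets' samples — the analysis always runs on concatenated
samples, never on averaged per-set results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .consensus import ConsensusResult, consensus_from_results
from .data_model import CTTable, collapse_technical_reps, ct_to_quantity
from .expression import ExpressionResult, compare_normalizers, ddct_expression
from .gene_number import GeneCountResult, gene_count_analysis
from .stability import METHODS, StabilityResult, run_all_methods

logger = logging.getLogger(__name__)

#: membership of the pooled condition sets
BIOTIC_SETS = ["developmental_stages", "larval_tissues", "adult_tissues", "densities"]
ABIOTIC_SETS = ["photoperiod", "temperature"]
POOLED = {"all_biotic": BIOTIC_SETS, "all_abiotic": ABIOTIC_SETS}


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the CT table itself."""

    condition_sets: Sequence[str] | None = None  # None = all present + pooled
    include_pooled: bool = True
    methods: Sequence[str] = METHODS
    cutoff: float = 0.15
    normfinder_grouping: str = "auto"  # auto | levels | single
    bestkeeper_sd: str = "mad"
    default_base: float = 2.0
    use_gene_efficiency: bool = False
    average_bio_reps: bool = False
    target: str | None = None
    target_refs: Sequence[Sequence[str]] | None = None
    calibrator: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ConditionSetReport:
    condition_set: str
    n_samples: int
    stability: dict[str, StabilityResult]
    consensus: ConsensusResult
    gene_count: GeneCountResult
    expression: list[ExpressionResult] = field(default_factory=list)
    normalizer_ratios: pd.DataFrame | None = None


def _average_bio_reps(table: CTTable) -> CTTable:
    """Optionally average biological replicates into one sample per level."""
    df = table.data.copy()
    df["sample_id"] = df["condition_set"] + ":" + df["level"]
    df["bio_rep"] = 1
    grouped = (
        df.groupby(["sample_id", "condition_set", "level", "bio_rep", "gene"])
        .agg(ct=("ct", "mean"))
        .reset_index()
    )
    grouped["tech_rep"] = 1
    return CTTable(grouped, genes=table.genes.values())


def analyze_condition_set(
    table: CTTable, cfg: RunConfig, condition_set: str
) -> ConditionSetReport:
    """Run the full analysis on one (possibly pooled) condition set."""
    if len(list(cfg.methods)) < 2:
        raise ValueError("the consensus needs at least 2 stability methods")
    collapsed = collapse_technical_reps(table)
    if cfg.average_bio_reps:
        collapsed = _average_bio_reps(collapsed)
    q = ct_to_quantity(
        collapsed,
        default_base=cfg.default_base,
        use_gene_efficiency=cfg.use_gene_efficiency,
    )
    if cfg.normfinder_grouping == "auto":
        grouping: object = "auto"
    elif cfg.normfinder_grouping == "levels":
        grouping = collapsed.levels(qualified=True)
    elif cfg.normfinder_grouping == "single":
        grouping = None
    else:
        raise ValueError(f"unknown normfinder grouping {cfg.normfinder_grouping!r}")

    stability = run_all_methods(
        collapsed,
        q=q,
        methods=cfg.methods,
        normfinder_groups=grouping,
        bestkeeper_sd=cfg.bestkeeper_sd,
    )
    cons = consensus_from_results(stability)

    if "genorm" in stability:
        ordered = stability["genorm"].detail.stability_order
    else:
        ordered = cons.ordering
    gene_count = gene_count_analysis(q, ordered, cutoff=cfg.cutoff)

    expression: list[ExpressionResult] = []
    ratios = None
    if cfg.target is not None and cfg.target in collapsed.gene_symbols:
        ref_sets = cfg.target_refs or [gene_count.recommended_genes[:2]]
        expression = [
            ddct_expression(collapsed, cfg.target, refs, cfg.calibrator)
            for refs in ref_sets
        ]
        if len(ref_sets) >= 2:
            ratios = compare_normalizers(
                collapsed, cfg.target, ref_sets, cfg.calibrator
            )

    return ConditionSetReport(
        condition_set=condition_set,
        n_samples=len(collapsed.sample_ids),
        stability=stability,
        consensus=cons,
        gene_count=gene_count,
        expression=expression,
        normalizer_ratios=ratios,
    )


def run_pipeline(
    table: CTTable, cfg: RunConfig, out_dir: str | Path | None = None
) -> dict[str, ConditionSetReport]:
    """Analyze every requested condition set; write the report bundle.

    A failure in one condition set logs a diagnostic and the run continues
    with the remaining sets; the manifest records which sets failed.
    """
    present = table.condition_sets
    if cfg.condition_sets is not None:
        requested = list(cfg.condition_sets)
    else:
        requested = list(present)
        if cfg.include_pooled:
            for pooled, members in POOLED.items():
                if sum(m in present for m in members) >= 2:
                    requested.append(pooled)
            if len(present) >= 2:
                requested.append("all_samples")

    reports: dict[str, ConditionSetReport] = {}
    failures: dict[str, str] = {}
    for name in requested:
        try:
            if name == "all_samples":
                sub = table
            elif name in POOLED:
                members = [m for m in POOLED[name] if m in present]
                sub = table.select(members)
            else:
                sub = table.select(name)
            reports[name] = analyze_condition_set(sub, cfg, name)
        except Exception as exc:  # deliberate: one bad set must not kill the run
            logger.error("condition set %s failed: %s", name, exc)
            failures[name] = str(exc)

    if out_dir is not None:
        write_report_bundle(reports, cfg, failures, out_dir)
    if not reports:
        raise RuntimeError(f"every condition set failed: {failures}")
    return reports


def write_report_bundle(
    reports: dict[str, ConditionSetReport],
    cfg: RunConfig,
    failures: dict[str, str],
    out_dir: str | Path,
) -> None:
    """Deterministic delimited tables plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rep in sorted(reports.items()):
        stab = pd.concat([r.to_frame() for r in rep.stability.values()])
        # rows ordered by consensus final rank, then symbol, within method
        order = {g: i for i, g in enumerate(rep.consensus.ordering)}
        stab = stab.sort_values(
            ["method", "gene"], key=lambda c: c.map(order) if c.name == "gene" else c
        )
        stab.to_csv(out / f"stability_{name}.tsv", sep="\t", index=False)
        rep.consensus.to_frame().to_csv(
            out / f"consensus_{name}.tsv", sep="\t", index=False
        )
        gc = rep.gene_count
        gc_frame = pd.DataFrame(
            {
                "n": gc.v.index,
                "V": gc.v.values,
                "cutoff": gc.cutoff,
                "chosen_n": gc.chosen_n,
                "rule_used": gc.rule_used,
                "nf_correlation_r_log2": gc.nf_correlation_r,
                "nf_correlation_r_linear": gc.nf_correlation_r_linear,
            }
        )
        gc_frame.to_csv(out / f"gene_count_{name}.tsv", sep="\t", index=False)
        if rep.expression:
            rows = []
            for er in rep.expression:
                for level, s in er.group_stats.iterrows():
                    rows.append(
                        {
                            "normalizer": er.normalizer_label,
                            "level": level,
                            "mean": s["mean"],
                            "sd": s["sd"],
                            "n": int(s["n"]),
                            "calibrator": er.calibrator,
                        }
                    )
            pd.DataFrame(rows).to_csv(
                out / f"expression_{name}.tsv", sep="\t", index=False
            )

    manifest = {
        "condition_sets": {
            name: {
                "n_samples": rep.n_samples,
                "chosen_n": rep.gene_count.chosen_n,
                "rule_used": rep.gene_count.rule_used,
                "top3": rep.consensus.top3,
            }
            for name, rep in sorted(reports.items())
        },
        "failures": failures,
        "settings": {
            "methods": list(cfg.methods),
            "cutoff": cfg.cutoff,
            "normfinder_grouping": cfg.normfinder_grouping,
            "bestkeeper_sd": cfg.bestkeeper_sd,
            "genorm_tie_break": "exclude lexicographically last symbol",
            "rank_ties": "min-tie competition ranking",
            "default_base": cfg.default_base,
            "use_gene_efficiency": cfg.use_gene_efficiency,
            "average_bio_reps": cfg.average_bio_reps,
            "seed": cfg.seed,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
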