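"""CT (cycle-threshold) tables: parsing, validation and transforms.

The raw input of the whole pipeline is a table of CT values per candidate
reference gene and sample, with sample metadata (condition set, condition
level, biological replicate, optional technical replicate).  This module
parses delimited text in long or wide layout, collapses technical replicates
to per-(gene, sample) mean CT, and converts CT to the relative quantities
``Q = E**(CTmin - CT)`` that geNorm-style analyses operate on.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of the long layout, in canonical order
LONG_COLUMNS = ["sample_id", "condition_set", "level", "bio_rep", "gene", "ct"]
#: sample-metadata columns shared by both layouts
META_COLUMNS = ["sample_id", "condition_set", "level", "bio_rep"]

_NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "na"}

# CT values outside this open interval are physically implausible (a qPCR run
# is 40-45 cycles) and rejected outright.
CT_MIN, CT_MAX = 0.0, 45.0


@dataclass(frozen=True)
class GeneAssay:
    """One primer assay: gene symbol plus optional amplification efficiency.

    ``efficiency_percent`` is the percent amplification efficiency from a
    dilution standard curve; 100 means perfect doubling per cycle.  The
    per-cycle fold change is ``E = 1 + efficiency_percent / 100``.
    """

    symbol: str
    efficiency_percent: float | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.efficiency_percent is not None:
            e = float(self.efficiency_percent)
            if not (50.0 < e <= 150.0):
                raise ValueError(
                    f"gene {self.symbol!r}: efficiency {e}% outside (50, 150]"
                )

    def base(self, default: float = 2.0, use_efficiency: bool = False) -> float:
        """Per-cycle amplification factor E used in the CT -> quantity transform."""
        if use_efficiency and self.efficiency_percent is not None:
            return 1.0 + float(self.efficiency_percent) / 100.0
        return float(default)


@dataclass(frozen=True)
class Sample:
    """One biological sample: a level of a condition set, one bio replicate."""

    sample_id: str
    condition_set: str
    level: str
    bio_rep: int


class CTTable:
    """Validated long-format CT table.

    Internally a canonicalised pandas DataFrame with columns
    ``sample_id, condition_set, level, bio_rep, tech_rep, gene, ct``
    (plus ``rep_count`` after technical-replicate collapse), sorted by
    (gene, sample_id, tech_rep) so that equal datasets compare equal
    regardless of input row order.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        genes: Iterable[GeneAssay] | None = None,
    ) -> None:
        df = data.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CT table missing columns: {missing}")
        if "tech_rep" not in df.columns:
            df["tech_rep"] = 1
        df["bio_rep"] = df["bio_rep"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        df["ct"] = df["ct"].astype(float)

        dup = df.duplicated(subset=["sample_id", "gene", "tech_rep"], keep=False)
        if dup.any():
            first = df.loc[dup].iloc[0]
            raise ValueError(
                "duplicate CT cell for sample "
                f"{first['sample_id']!r}, gene {first['gene']!r}, "
                f"tech_rep {int(first['tech_rep'])}"
            )

        bad = df["ct"].notna() & ~df["ct"].between(CT_MIN, CT_MAX, inclusive="neither")
        if bad.any():
            v = df.loc[bad, "ct"].iloc[0]
            raise ValueError(f"CT value {v} outside ({CT_MIN}, {CT_MAX})")

        meta = df[META_COLUMNS].drop_duplicates()
        if meta["sample_id"].duplicated().any():
            sid = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"sample {sid!r} has inconsistent metadata rows")

        keep = LONG_COLUMNS + ["tech_rep"] + (
            ["rep_count"] if "rep_count" in df.columns else []
        )
        df = df[keep].sort_values(["gene", "sample_id", "tech_rep"]).reset_index(drop=True)
        self.data = df

        assays = {g.symbol: g for g in (genes or [])}
        self.genes: dict[str, GeneAssay] = {
            sym: assays.get(sym, GeneAssay(sym)) for sym in self.gene_symbols
        }

    # -- structure -----------------------------------------------------------

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def samples(self) -> list[Sample]:
        meta = self.data[META_COLUMNS].drop_duplicates().sort_values("sample_id")
        return [
            Sample(r.sample_id, r.condition_set, r.level, int(r.bio_rep))
            for r in meta.itertuples()
        ]

    @property
    def condition_sets(self) -> list[str]:
        return sorted(self.data["condition_set"].unique())

    def levels(self, qualified: bool = False) -> pd.Series:
        """Per-sample condition level, indexed by sample_id (sorted).

        With ``qualified=True`` levels are prefixed with their condition set,
        which keeps groups distinct when condition sets are pooled.
        """
        meta = (
            self.data[META_COLUMNS]
            .drop_duplicates()
            .set_index("sample_id")
            .sort_index()
        )
        if qualified:
            return meta["condition_set"] + ":" + meta["level"]
        return meta["level"]

    @property
    def is_collapsed(self) -> bool:
        return not self.data.duplicated(subset=["sample_id", "gene"]).any()

    @property
    def matrix(self) -> pd.DataFrame:
        """Gene x sample CT matrix; requires a collapsed, complete table."""
        if not self.is_collapsed:
            raise ValueError("collapse technical replicates before using .matrix")
        m = self.data.pivot(index="gene", columns="sample_id", values="ct")
        m = m.sort_index().sort_index(axis=1)
        if m.isna().any().any():
            raise ValueError("CT matrix has missing cells")
        return m

    def select(self, condition_sets: str | Sequence[str]) -> "CTTable":
        """Subset to one or more condition sets (pooled sets are unions)."""
        if isinstance(condition_sets, str):
            condition_sets = [condition_sets]
        sub = self.data[self.data["condition_set"].isin(condition_sets)]
        if sub.empty:
            raise ValueError(f"no samples in condition sets {list(condition_sets)}")
        return CTTable(sub, genes=self.genes.values())

    def with_genes(self, genes: Iterable[GeneAssay]) -> "CTTable":
        return CTTable(self.data, genes=genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CTTable):
            return NotImplemented
        cols = [c for c in self.data.columns if c in other.data.columns]
        return self.data[cols].equals(other.data[cols]) and self.genes == other.genes

    def __repr__(self) -> str:
        return (
            f"CTTable({len(self.gene_symbols)} genes x {len(self.sample_ids)} "
            f"samples, collapsed={self.is_collapsed})"
        )


@dataclass
class QuantityMatrix:
    """Relative quantities Q = E**(CTmin - CT), gene x sample.

    Per gene the minimum-CT (highest-expression) sample is the unit, so
    ``max(q) == 1`` in every row and all entries are positive.
    """

    q: pd.DataFrame
    base_per_gene: pd.Series

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)

    def log2(self) -> pd.DataFrame:
        """Log2 quantities, the scale NormFinder and geNorm work on."""
        return np.log2(self.q)


# -- parsing ----------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_ct_column(values: pd.Series, line_offset: int = 2) -> pd.Series:
    """Parse CT strings to floats; NA markers become NaN; anything else is a
    hard error reported with its 1-based file line number."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        s = str(v).strip()
        if s in _NA_STRINGS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric CT value {s!r} at line {i + line_offset}"
            ) from None
    return pd.Series(out, index=values.index)


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    delimiter: str | None = None,
    genes: Iterable[GeneAssay] | None = None,
) -> CTTable:
    """Read a CT table from delimited text (UTF-8, comma or tab).

    Parameters
    ----------
    path
        Input file.  The delimiter is auto-detected between comma and tab
        unless ``delimiter`` overrides it.
    layout
        ``"long"``: columns ``sample_id, condition_set, level, bio_rep,
        [tech_rep,] gene, ct``.  ``"wide"``: the sample-metadata columns
        followed by one column per gene symbol.
    genes
        Optional :class:`GeneAssay` metadata (efficiencies) to attach.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"long layout missing columns: {missing}")
        df = raw.copy()
        df["ct"] = _parse_ct_column(df["ct"])
    elif layout == "wide":
        missing = [c for c in META_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"wide layout missing columns: {missing}")
        id_cols = [c for c in raw.columns if c in META_COLUMNS + ["tech_rep"]]
        gene_cols = [c for c in raw.columns if c not in id_cols]
        if not gene_cols:
            raise ValueError("wide layout has no gene columns")
        df = raw.melt(
            id_vars=id_cols, value_vars=gene_cols, var_name="gene", value_name="ct"
        )
        df["ct"] = _parse_ct_column(df["ct"], line_offset=0)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")

    return CTTable(df, genes=genes)


def write_ct_table(table: CTTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a CTTable back to long-format delimited text."""
    cols = [c for c in LONG_COLUMNS + ["tech_rep"] if c in table.data.columns]
    table.data[cols].to_csv(path, sep=delimiter, index=False)


# -- transforms -------------------------------------------------------------


def collapse_technical_reps(table: CTTable) -> CTTable:
    """Average technical replicates to one CT per (gene, sample).

    Genes left with any missing (gene, sample) cell after averaging are
    dropped with a logged warning: every downstream stability method assumes
    a complete matrix.  Idempotent on already-collapsed tables.
    """
    df = table.data
    grouped = (
        df.groupby(META_COLUMNS + ["gene"], sort=False)
        .agg(ct=("ct", "mean"), rep_count=("ct", "size"))
        .reset_index()
    )
    wide = grouped.pivot(index="gene", columns="sample_id", values="ct")
    # a sample entirely absent for a gene also counts as missing
    wide = wide.reindex(columns=sorted(df["sample_id"].unique()))
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        logger.warning(
            "dropping genes with missing CT cells after collapse: %s", incomplete
        )
        grouped = grouped[~grouped["gene"].isin(incomplete)]
    if grouped.empty:
        raise ValueError("no complete genes remain after replicate collapse")
    grouped = grouped.drop(columns=[], errors="ignore")
    grouped["tech_rep"] = 1
    return CTTable(grouped, genes=[g for s, g in table.genes.items() if s not in incomplete])


def ct_to_quantity(
    table: CTTable,
    default_base: float = 2.0,
    use_gene_efficiency: bool = False,
) -> QuantityMatrix:
    """Convert CT to relative quantities ``q[i, s] = E_i**(CTmin_i - CT[i, s])``.

    ``E_i`` is the per-gene amplification base: ``1 + efficiency/100`` when
    ``use_gene_efficiency`` is set and the gene carries an efficiency, else
    ``default_base`` (2 = perfect doubling, the convention of the classical
    stability tools).
    """
    m = table.matrix
    bases = pd.Series(
        {
            sym: table.genes[sym].base(default_base, use_gene_efficiency)
            for sym in m.index
        },
        name="base",
    )
    if (bases <= 1.0).any():
        bad = bases[bases <= 1.0].index.tolist()
        raise ValueError(f"amplification base must exceed 1; offending genes: {bad}")
    ct_min = m.min(axis=1)
    q = pd.DataFrame(
        np.power(bases.values[:, None], (ct_min.values[:, None] - m.values)),
        index=m.index,
        columns=m.columns,
    )
    return QuantityMatrix(q=q, base_per_gene=bases)


def summarize_ct(table: CTTable) -> pd.DataFrame:
    """Per-gene CT summary (mean, min, max, sd with n-1 divisor)."""
    m = table.matrix
    return pd.DataFrame(
        {
            "mean": m.mean(axis=1),
            "min": m.min(axis=1),
            "max": m.max(axis=1),
            "sd": m.std(axis=1, ddof=1),
        }
    )
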