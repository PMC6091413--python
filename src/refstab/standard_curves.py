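"""Dilution standard curves and amplification efficiency.

A 10-fold dilution series of pooled cDNA gives points (log10 dilution, CT).
An ordinary least-squares line ``CT = intercept + slope * log10_dilution``
has slope -1/log10(E) where E is the per-cycle amplification factor, so the
percent efficiency is ``E(%) = (10**(-1/slope) - 1) * 100``.  A slope of
-3.32 corresponds to perfect doubling (100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float | None
    n_points: int

    @property
    def valid(self) -> bool:
        return self.slope < 0 and self.efficiency_percent is not None


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    ``E(%) = (10**(-1/slope) - 1) * 100``; slope -3.321928 gives exactly 100.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(
    points: list[tuple[float, float]] | np.ndarray, gene: str = ""
) -> StandardCurve:
    """OLS fit of CT on log10 dilution; at least 3 distinct dilution levels.

    A non-negative slope marks the curve invalid (efficiency absent) rather
    than producing a nonsensical efficiency.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (log10_dilution, ct) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r_squared = float(res.rvalue) ** 2
    eff = efficiency_from_slope(slope) if slope < 0 else None
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        efficiency_percent=eff,
        n_points=len(x),
    )


def read_dilution_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a dilution-series table with columns gene, log10_dilution, ct."""
    path = Path(path)
    sep = delimiter
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"gene", "log10_dilution", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dilution table missing columns: {sorted(missing)}")
    return df


def fit_all_curves(df: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from a tidy dilution table."""
    return {
        gene: fit_standard_curve(sub[["log10_dilution", "ct"]].to_numpy(), gene)
        for gene, sub in df.groupby("gene", sort=True)
    }
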