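"""Synthetic CT datasets with planted ground truth.

No raw CT data accompany the published stability tables, so every pipeline
stage is exercised on simulated data built to the same experimental designs:
ten genes whose mean CTs span roughly 10-26 cycles, condition sets of 8
developmental stages / 4 larval tissues / 6 adult tissues / 4 rearing
densities / 2 photoperiods / 2 temperatures, three biological replicates per
level and three technical replicates per reaction.

The generative model on the CT scale is

    CT[i, (l, r, t)] = baseline_i + b_il + e_ilr + u_ilrt

with per-level drift ``b_il ~ N(0, tau_i^2)`` (an unstable gene has large
tau), biological noise ``e ~ N(0, sigma_bio_i^2)`` and technical noise
``u ~ N(0, sigma_tech^2)``.  CT is log-scale fluorescence, so additive
Gaussian error is the standard assumption.  The "true" stability order is
ascending ``sqrt(tau_i^2 + sigma_bio_i^2)`` — exactly the quantity the
pairwise-SD methods estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import published
from .data_model import CTTable, GeneAssay

#: level labels per experimental design
DESIGN_LEVELS = {
    "developmental_stages": ["L4", "L5", "L6", "PP", "P1", "P5", "P9", "A0"],
    "larval_tissues": ["brain", "epidermis", "fat_body", "alimentary_canal"],
    "adult_tissues": [
        "male_brain", "female_brain", "testis",
        "ovary", "male_fat_body", "female_fat_body",
    ],
    "densities": ["1_per_jar", "10_per_jar", "20_per_jar", "30_per_jar"],
    "photoperiod": ["8L16D", "16L8D"],
    "temperature": ["18C", "25C"],
}

#: default per-level drift SD (CT units) per gene: the rRNAs, beta-actin and
#: TBP drift with condition, the rest are comparatively stable — mirroring
#: the instability pattern the published rankings show.
DEFAULT_DRIFT_SD = {
    "GAPDH": 0.30, "18S": 1.20, "28S": 1.40, "EF": 0.15, "RPL12": 0.20,
    "beta-TUB": 0.20, "ATPase": 0.35, "TBP": 0.60, "beta-ACT": 0.80,
    "CypA": 0.25,
}

DEFAULT_NOISE_SD = 0.3   # biological replicate SD, CT units
DEFAULT_TECH_SD = 0.15   # technical replicate SD, CT units


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    baseline_ct: float
    drift_sd: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    efficiency_percent: float | None = None

    def __post_init__(self) -> None:
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError(f"gene {self.symbol!r}: SDs must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    genes: tuple[GeneSpec, ...]
    levels: tuple[str, ...]
    condition_set: str = "simulated"
    bio_reps: int = 3
    tech_reps: int = 3
    tech_sd: float = DEFAULT_TECH_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.tech_sd < 0:
            raise ValueError("tech_sd must be >= 0")
        if len({g.symbol for g in self.genes}) != len(self.genes):
            raise ValueError("gene symbols must be unique")


@dataclass
class GroundTruth:
    """Planted parameters stored alongside each simulated dataset."""

    config: SimulationConfig
    level_effects: pd.DataFrame  # gene x level, the realized b_il
    true_sd: pd.Series           # sqrt(tau^2 + sigma_bio^2) per gene
    true_order: list[str]        # ascending true_sd, ties by symbol

    def to_frame(self) -> pd.DataFrame:
        out = self.level_effects.copy()
        out["true_sd"] = self.true_sd
        return out


def simulate_ct_dataset(config: SimulationConfig) -> tuple[CTTable, GroundTruth]:
    """Draw one CT dataset from the generative model; (config, seed) fully
    determines the output."""
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    levels = list(config.levels)

    tau = np.array([g.drift_sd for g in genes])
    b = rng.normal(0.0, tau[:, None], size=(len(genes), len(levels)))

    rows = []
    for li, level in enumerate(levels):
        for r in range(1, config.bio_reps + 1):
            sample_id = f"{level}_r{r}"
            e = rng.normal(0.0, [g.noise_sd for g in genes])
            for gi, g in enumerate(genes):
                for t in range(1, config.tech_reps + 1):
                    u = rng.normal(0.0, config.tech_sd) if config.tech_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition_set": config.condition_set,
                            "level": level,
                            "bio_rep": r,
                            "tech_rep": t,
                            "gene": g.symbol,
                            "ct": g.baseline_ct + b[gi, li] + e[gi] + u,
                        }
                    )
    table = CTTable(
        pd.DataFrame(rows),
        genes=[
            GeneAssay(g.symbol, efficiency_percent=g.efficiency_percent)
            for g in genes
        ],
    )
    true_sd = pd.Series(
        {g.symbol: float(np.hypot(g.drift_sd, g.noise_sd)) for g in genes}
    )
    order = sorted(true_sd.index, key=lambda s: (true_sd[s], s))
    truth = GroundTruth(
        config=config,
        level_effects=pd.DataFrame(
            b, index=[g.symbol for g in genes], columns=levels
        ),
        true_sd=true_sd,
        true_order=order,
    )
    return table, truth


def simulate_standard_curve(
    true_efficiency_percent: float,
    n_levels: int = 4,
    sd: float = 0.0,
    seed: int = 0,
    intercept: float = 30.0,
) -> pd.DataFrame:
    """Dilution-series points for a known efficiency.

    The slope is ``-1 / log10(1 + E%/100)``; dilutions run 0, -1, -2, ...
    (10-fold steps) and Gaussian noise of SD ``sd`` is added to CT.
    """
    if n_levels < 3:
        raise ValueError("need at least 3 dilution levels")
    e = 1.0 + true_efficiency_percent / 100.0
    if e <= 1.0:
        raise ValueError("efficiency must exceed 0%")
    slope = -1.0 / np.log10(e)
    x = -np.arange(n_levels, dtype=float)
    rng = np.random.default_rng(seed)
    ct = intercept + slope * x + (rng.normal(0.0, sd, n_levels) if sd > 0 else 0.0)
    return pd.DataFrame({"log10_dilution": x, "ct": ct})


def design_preset(name: str, seed: int = 0) -> SimulationConfig:
    """Simulation preset for one of the study's experimental designs.

    Ten genes with the published symbols, baseline CTs at the published mean
    CT of each gene (spanning ~10-26 cycles), published primer efficiencies,
    3 biological x 3 technical replicates, and the default drift/noise SDs.
    """
    if name not in DESIGN_LEVELS:
        raise KeyError(
            f"unknown design {name!r}; valid presets: {sorted(DESIGN_LEVELS)}"
        )
    genes = tuple(
        GeneSpec(
            symbol=sym,
            baseline_ct=published.MEAN_CT[sym],
            drift_sd=DEFAULT_DRIFT_SD[sym],
            noise_sd=DEFAULT_NOISE_SD,
            efficiency_percent=published.EFFICIENCY_PERCENT[sym],
        )
        for sym in published.GENES
    )
    return SimulationConfig(
        genes=genes,
        levels=tuple(DESIGN_LEVELS[name]),
        condition_set=name,
        bio_reps=3,
        tech_reps=3,
        tech_sd=DEFAULT_TECH_SD,
        seed=seed,
    )


def all_design_presets(seed: int = 0) -> dict[str, SimulationConfig]:
    """One preset per design, with per-design sub-seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    out = {}
    for name in DESIGN_LEVELS:
        out[name] = replace(design_preset(name), seed=int(rng.integers(2**31)))
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar text file with the planted parameters."""
    truth.to_frame().to_csv(path, sep="\t")
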