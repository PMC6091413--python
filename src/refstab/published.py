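"""Published stability tables for ten candidate reference genes in the
oriental armyworm (*Mythimna separata*).

The published study scored ten commonly used reference genes (18S and 28S
rRNA, RPL12, GAPDH, CypA, beta-actin, beta-tubulin, V-ATPase subunit H, TBP
and EF-1alpha) with geNorm, NormFinder, BestKeeper and the comparative dCT
method across nine condition sets (developmental stages, larval and adult
tissues, rearing densities, photoperiod and temperature regimes, and pooled
biotic / abiotic / all-sample sets).  The raw CT data were not deposited,
but the per-method stability values and ranks were printed in full; this
module carries them verbatim as the worked-example inputs for the consensus
and ranking operations.

Values are stored exactly as printed.  A few printed rank entries are
internally inconsistent with their own stability columns (e.g. the dCT
ranks of 18S and 28S under larval tissues are swapped, and two NormFinder
rank-2 entries appear in the all-samples table); they are kept as printed
and are not used as rank-consistency fixtures.
"""

from __future__ import annotations

import pandas as pd

#: gene symbols, in the published assay-table order
GENES = [
    "GAPDH", "18S", "28S", "EF", "RPL12",
    "beta-TUB", "ATPase", "TBP", "beta-ACT", "CypA",
]

#: primer amplification efficiency (%) per gene, from the published assay table
EFFICIENCY_PERCENT = {
    "GAPDH": 105.8, "18S": 106.1, "28S": 98.8, "EF": 102.1, "RPL12": 100.9,
    "beta-TUB": 108.9, "ATPase": 102.5, "TBP": 98.3, "beta-ACT": 96.8,
    "CypA": 101.1,
}

#: mean CT per gene across all treatments (rRNAs most abundant, TBP least)
MEAN_CT = {
    "28S": 10.7, "18S": 12.4, "beta-ACT": 15.8, "CypA": 18.7, "GAPDH": 18.9,
    "beta-TUB": 19.8, "RPL12": 19.8, "ATPase": 21.6, "EF": 24.5, "TBP": 25.9,
}

METHOD_COLUMNS = ["genorm", "normfinder", "bestkeeper", "deltact"]

# Per condition set, per gene:
# (genorm stability, rank, normfinder stability, rank,
#  bestkeeper stability, rank, deltact stability, rank) — as printed.
_TABLES: dict[str, dict[str, tuple]] = {
    "developmental_stages": {
        "GAPDH":    (1.138, 5, 1.002, 4, 0.88, 1, 1.94, 4),
        "18S":      (1.876, 9, 2.288, 8, 2.72, 9, 2.89, 9),
        "28S":      (2.364, 10, 4.168, 10, 4.12, 10, 4.32, 10),
        "EF":       (0.901, 3, 0.286, 1, 1.04, 3, 1.77, 2),
        "RPL12":    (0.375, 1, 1.186, 5, 1.06, 4, 1.96, 5),
        "beta-TUB": (0.964, 4, 0.335, 2, 1.12, 5, 1.73, 1),
        "ATPase":   (1.26, 6, 0.867, 3, 1.17, 6, 2.01, 6),
        "TBP":      (1.377, 7, 1.868, 7, 1.2, 7, 2.38, 7),
        "beta-ACT": (1.57, 8, 2.321, 9, 1.59, 8, 2.71, 8),
        "CypA":     (0.375, 1, 1.197, 6, 0.89, 2, 1.93, 3),
    },
    "larval_tissues": {
        "GAPDH":    (0.944, 6, 1.564, 7, 0.79, 5, 1.91, 7),
        "18S":      (1.612, 9, 1.898, 9, 1.96, 9, 2.16, 5),
        "28S":      (0.626, 3, 1.213, 5, 0.62, 2, 1.58, 9),
        "EF":       (0.528, 1, 0.577, 2, 0.28, 1, 1.35, 2),
        "RPL12":    (0.528, 1, 1.043, 4, 0.62, 3, 1.52, 3),
        "beta-TUB": (1.144, 7, 0.642, 3, 1.12, 7, 1.53, 4),
        "ATPase":   (1.41, 8, 1.707, 8, 1.84, 8, 2.1, 8),
        "TBP":      (0.674, 4, 1.505, 6, 0.84, 6, 1.77, 6),
        "beta-ACT": (1.761, 10, 2.128, 10, 2.01, 10, 2.35, 10),
        "CypA":     (0.772, 5, 0.292, 1, 0.67, 4, 1.33, 1),
    },
    "adult_tissues": {
        "GAPDH":    (0.888, 7, 0.629, 3, 1.27, 7, 1.02, 4),
        "18S":      (0.815, 6, 0.643, 5, 1.17, 3, 1.03, 6),
        "28S":      (0.949, 8, 0.982, 8, 1.68, 9, 1.23, 9),
        "EF":       (0.368, 1, 0.533, 1, 1.24, 6, 0.92, 1),
        "RPL12":    (0.663, 5, 1.002, 9, 1.76, 10, 1.2, 8),
        "beta-TUB": (0.386, 3, 0.629, 4, 1.18, 5, 0.97, 3),
        "ATPase":   (1.008, 9, 0.867, 7, 0.97, 2, 1.13, 7),
        "TBP":      (0.368, 1, 0.534, 2, 1.18, 4, 0.93, 2),
        "beta-ACT": (1.085, 10, 1.244, 10, 0.83, 1, 1.39, 10),
        "CypA":     (0.522, 4, 0.727, 6, 1.43, 8, 1.03, 5),
    },
    "densities": {
        "GAPDH":    (0.301, 6, 0.305, 6, 0.24, 4, 0.51, 6),
        "18S":      (0.337, 7, 0.436, 8, 0.43, 7, 0.55, 8),
        "28S":      (0.229, 3, 0.158, 3, 0.24, 5, 0.42, 2),
        "EF":       (0.265, 4, 0.171, 4, 0.13, 1, 0.47, 4),
        "RPL12":    (0.16, 1, 0.017, 1, 0.2, 2, 0.43, 3),
        "beta-TUB": (0.16, 1, 0.031, 2, 0.27, 6, 0.42, 1),
        "ATPase":   (0.36, 8, 0.342, 7, 0.44, 8, 0.51, 7),
        "TBP":      (0.566, 10, 1.244, 10, 0.82, 10, 1.27, 10),
        "beta-ACT": (0.277, 5, 0.172, 5, 0.23, 3, 0.47, 5),
        "CypA":     (0.391, 9, 0.519, 9, 0.57, 9, 0.62, 9),
    },
    "all_biotic": {
        "GAPDH":    (1.116, 5, 1.039, 5, 1.16, 4, 1.97, 5),
        "18S":      (1.987, 9, 2.624, 9, 3.08, 10, 3.07, 9),
        "28S":      (2.315, 10, 3.332, 10, 2.72, 9, 3.63, 10),
        "EF":       (0.837, 3, 0.872, 2, 0.91, 1, 1.81, 2),
        "RPL12":    (0.646, 1, 1.045, 6, 1.25, 5, 1.89, 4),
        "beta-TUB": (0.95, 4, 0.39, 1, 1.43, 7, 1.75, 1),
        "ATPase":   (1.411, 7, 0.996, 3, 1.31, 6, 2.03, 6),
        "TBP":      (1.284, 6, 1.958, 7, 1.04, 2, 2.42, 7),
        "beta-ACT": (1.669, 8, 2.232, 8, 2.36, 8, 2.72, 8),
        "CypA":     (0.646, 1, 1.013, 4, 1.05, 3, 1.85, 3),
    },
    "photoperiod": {
        "GAPDH":    (0.179, 1, 1.657, 6, 0.58, 4, 1.97, 4),
        "18S":      (2.504, 10, 5.034, 10, 5.08, 10, 5.07, 10),
        "28S":      (1.863, 9, 3.608, 9, 3.94, 9, 3.96, 9),
        "EF":       (0.581, 6, 0.059, 1, 0.27, 2, 1.82, 1),
        "RPL12":    (0.293, 4, 1.188, 4, 0.25, 1, 1.83, 2),
        "beta-TUB": (0.963, 7, 0.117, 2, 1.31, 7, 2.09, 6),
        "ATPase":   (1.169, 8, 0.117, 3, 1.43, 8, 2.14, 7),
        "TBP":      (0.408, 5, 0.177, 8, 0.97, 6, 2.32, 8),
        "beta-ACT": (0.179, 1, 2.177, 7, 0.61, 5, 1.98, 5),
        "CypA":     (0.228, 3, 1.696, 5, 0.42, 3, 1.88, 3),
    },
    "temperature": {
        "GAPDH":    (0.704, 5, 1.396, 5, 0.77, 5, 1.96, 4),
        "18S":      (2.689, 10, 5.316, 10, 4.99, 10, 5.36, 10),
        "28S":      (2.021, 9, 5.064, 9, 4.79, 9, 5.17, 9),
        "EF":       (0.43, 3, 0.173, 3, 0.21, 1, 1.86, 2),
        "RPL12":    (0.537, 4, 0.669, 4, 0.33, 3, 1.85, 1),
        "beta-TUB": (0.181, 1, 0.09, 1, 0.32, 2, 1.94, 3),
        "ATPase":   (0.181, 1, 0.09, 2, 0.43, 4, 2.0, 5),
        "TBP":      (0.946, 8, 2.327, 8, 1.45, 8, 2.5, 8),
        "beta-ACT": (0.853, 7, 1.931, 7, 1.15, 7, 2.23, 7),
        "CypA":     (0.767, 6, 1.539, 6, 0.86, 6, 2.02, 6),
    },
    "all_abiotic": {
        "GAPDH":    (0.384, 3, 1.458, 6, 0.68, 4, 1.94, 4),
        "18S":      (2.546, 10, 4.937, 10, 5.04, 10, 5.01, 10),
        "28S":      (1.931, 9, 4.222, 9, 4.36, 9, 4.45, 9),
        "EF":       (0.689, 6, 0.238, 3, 0.30, 2, 1.81, 1),
        "RPL12":    (0.471, 4, 0.917, 4, 0.29, 1, 1.82, 2),
        "beta-TUB": (0.938, 7, 0.160, 1, 0.81, 5, 2.00, 5),
        "ATPase":   (1.084, 8, 0.160, 2, 0.93, 7, 2.08, 7),
        "TBP":      (0.557, 5, 2.184, 8, 1.21, 8, 2.36, 8),
        "beta-ACT": (0.350, 1, 1.760, 7, 0.88, 6, 2.07, 6),
        "CypA":     (0.350, 1, 1.455, 5, 0.64, 3, 1.93, 3),
    },
    "all_samples": {
        "GAPDH":    (1.148, 5, 1.242, 6, 1.14, 5, 2.14, 5),
        "18S":      (2.102, 9, 3.049, 9, 3.38, 10, 3.5, 9),
        "28S":      (2.49, 10, 3.759, 10, 3.29, 9, 4.04, 10),
        "EF":       (0.823, 3, 0.779, 2, 0.85, 1, 1.89, 2),
        "RPL12":    (0.625, 1, 1.005, 4, 1.1, 3, 1.96, 4),
        "beta-TUB": (0.97, 4, 0.209, 1, 1.37, 7, 1.88, 1),
        "ATPase":   (1.408, 7, 0.926, 3, 1.28, 6, 2.14, 6),
        "TBP":      (1.274, 6, 1.939, 7, 1.12, 4, 2.45, 7),
        "beta-ACT": (1.68, 8, 2.437, 8, 2.35, 8, 2.94, 8),
        "CypA":     (0.625, 1, 1.068, 2, 0.99, 2, 1.95, 3),
    },
}

#: published comprehensive (geometric-mean consensus) orderings, best first
CONSENSUS_ORDER = {
    "developmental_stages": [
        "EF", "CypA", "beta-TUB", "GAPDH", "RPL12",
        "ATPase", "TBP", "beta-ACT", "18S", "28S",
    ],
    "larval_tissues": [
        "EF", "CypA", "RPL12", "28S", "beta-TUB",
        "TBP", "GAPDH", "ATPase", "18S", "beta-ACT",
    ],
    "adult_tissues": [
        "EF", "TBP", "beta-TUB", "18S", "GAPDH",
        "ATPase", "CypA", "beta-ACT", "RPL12", "28S",
    ],
    "densities": [
        "RPL12", "beta-TUB", "EF", "28S", "beta-ACT",
        "GAPDH", "18S", "ATPase", "CypA", "TBP",
    ],
    "all_biotic": [
        "EF", "beta-TUB", "CypA", "RPL12", "GAPDH",
        "TBP", "ATPase", "beta-ACT", "18S", "28S",
    ],
    "photoperiod": [
        "EF", "RPL12", "GAPDH", "CypA", "beta-ACT",
        "beta-TUB", "ATPase", "TBP", "28S", "18S",
    ],
    "temperature": [
        "beta-TUB", "EF", "ATPase", "RPL12", "GAPDH",
        "CypA", "beta-ACT", "TBP", "28S", "18S",
    ],
    "all_abiotic": [
        "RPL12", "EF", "CypA", "beta-TUB", "beta-ACT",
        "GAPDH", "ATPase", "TBP", "28S", "18S",
    ],
    "all_samples": [
        "EF", "beta-TUB", "CypA", "RPL12", "GAPDH",
        "ATPase", "TBP", "beta-ACT", "18S", "28S",
    ],
}

CONDITION_SETS = list(_TABLES)


def published_table(condition_set: str) -> pd.DataFrame:
    """Full printed table for one condition set: per-gene stability and rank
    columns for each of the four methods."""
    if condition_set not in _TABLES:
        raise KeyError(
            f"unknown condition set {condition_set!r}; "
            f"available: {CONDITION_SETS}"
        )
    cols = []
    for m in METHOD_COLUMNS:
        cols += [f"{m}_stability", f"{m}_rank"]
    df = pd.DataFrame.from_dict(_TABLES[condition_set], orient="index", columns=cols)
    return df.loc[GENES]


def published_ranks(condition_set: str) -> pd.DataFrame:
    """Gene x method integer ranks as printed, ready for the consensus."""
    t = published_table(condition_set)
    ranks = t[[f"{m}_rank" for m in METHOD_COLUMNS]].astype(int)
    ranks.columns = METHOD_COLUMNS
    return ranks


def published_stabilities(condition_set: str) -> pd.DataFrame:
    """Gene x method stability values as printed."""
    t = published_table(condition_set)
    stab = t[[f"{m}_stability" for m in METHOD_COLUMNS]]
    stab.columns = METHOD_COLUMNS
    return stab
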