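"""How many reference genes per condition set: V ladders, the 0.15 rule and
the NF_3-vs-NF_opt correlation check.

Reads the report bundle written by 03_stability.py and prints, per set, the
pairwise-variation ladder, the chosen gene count with the rule that fired,
and the Pearson correlation between the 3-gene and chosen-count
normalization factors (computed on log2 NF; the linear-scale r is reported
alongside).  A high r says three genes already normalize as well as the
formally optimal count.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
REPORT = ROOT / "results" / "report"


def main() -> None:
    files = sorted(REPORT.glob("gene_count_*.tsv"))
    if not files:
        raise SystemExit("run analysis/03_stability.py first")
    summary = []
    for f in files:
        name = f.stem.removeprefix("gene_count_")
        df = pd.read_csv(f, sep="\t")
        ladder = " ".join(f"V{int(n)}/{int(n) + 1}={v:.3f}" for n, v in zip(df["n"], df["V"]))
        row = df.iloc[0]
        summary.append(
            {
                "condition_set": name,
                "chosen_n": int(row["chosen_n"]),
                "rule": row["rule_used"],
                "r_log2": round(float(row["nf_correlation_r_log2"]), 3),
                "r_linear": round(float(row["nf_correlation_r_linear"]), 3),
            }
        )
        print(f"{name}: {ladder}")
    out = pd.DataFrame(summary)
    out.to_csv(REPORT / "gene_count_summary.tsv", sep="\t", index=False)
    print("\n" + out.to_string(index=False))


if __name__ == "__main__":
    main()
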