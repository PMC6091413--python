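# Methods

## The problem and the model

RT-qPCR reports a cycle threshold CT per reaction: the PCR cycle at which
fluorescence crosses a fixed threshold. CT is a log-scale abundance measure
— at amplification efficiency E (fold change per cycle) a one-cycle shift is
an E-fold change in template. A target gene's expression is meaningful only
relative to reference genes assumed stable across the compared conditions,
so the workflow here scores a candidate panel for stability, aggregates the
scores, decides how many references to use, and demonstrates the cost of a
bad choice on a target gene.

All stability statistics operate per *condition set*: one experimental
design (e.g. four larval tissues) whose levels are the groups being
compared. Technical replicates are averaged to one CT per (gene, sample)
first; biological replicates stay as separate samples by default (an
averaging option exists, and the choice is recorded in the run manifest,
because published workflows are ambiguous on this point).

### Quantities

geNorm-style methods work on relative quantities
`Q[i,s] = E_i^(CTmin_i − CT[i,s])`, anchored so each gene's best-expressed
sample is 1. The anchor is irrelevant: every downstream statistic uses only
ratios between samples (per-gene rescaling invariance is property-tested).
E defaults to 2 for every gene — the convention of the classical tools —
with per-gene standard-curve efficiencies available behind a flag.

### The four statistics (lower = more stable)

* **geNorm M.** For genes j, k let `V_jk = SD_s(log2 Q_j/Q_k)` (n−1
  divisor). A gene's M is the mean of its V against all panel partners.
  The least stable gene is excluded and M recomputed, repeatedly, until two
  genes remain. The *reported* stability of a gene is its M at the step it
  was excluded; the final pair cannot be distinguished by construction and
  share the last-step M and rank 1 — this convention is what produces the
  tied rank-1 pairs seen in published geNorm tables. Ties for the current
  worst M are broken by excluding the lexicographically last symbol
  (deterministic; noted in the manifest).
* **NormFinder.** On log2 quantities, center each sample across genes
  (z). Single group: per-gene variance s²_i is bias-corrected for the
  centring, `σ̂²_i = max(0, (s²_i − s̄²/(k−1))·k/(k−2))`, and stability is
  σ̂_i. With G ≥ 2 groups of sizes n_g: intergroup deviations
  `d̂_ig = z̄_ig − z̄_i·` (summing to zero over genes within each group),
  per-group σ̂²_ig via the same corrector, intergroup variance
  `γ̂² = max(0, Σd̂²/((k−1)(G−1)) − mean(σ̂²_ig/n_g))`, shrunk deviations
  `d̃ = d̂·γ̂²/(γ̂²+σ̂²/n_g)`, and stability
  `ρ_i = mean_g(|d̃_ig| + sqrt((σ̂²_ig/n_g)·γ̂²/(γ̂²+σ̂²_ig/n_g)))`.
  The estimator constants are validated by parameter recovery: mean
  relative error of σ̂ under 5% at k = 10, n = 1000, and a planted 2-CT
  group shift makes the affected gene worst in effectively every seed.
  Grouping default: condition levels when every level has ≥ 2 samples,
  else single-group mode (the grouping actually used is in the manifest).
* **BestKeeper.** Works on raw CT. The "SD" follows the original tool:
  mean absolute deviation from the arithmetic mean (a config switch gives
  the classical n−1 SD; the choice is printed in the manifest). The detail
  block carries descriptives, the per-sample index (geometric mean CT over
  genes) and each gene's Pearson r/p against it.
* **Comparative ΔCT.** `stability_i = mean_{j≠i} SD_s(CT_i − CT_j)`,
  on raw CT by definition. At E = 2 the full-panel geNorm M coincides with
  this statistic exactly (log2 quantity ratios *are* CT differences); that
  identity is the main cross-method oracle in the tests.

Ranks everywhere use min-tie competition ranking ("1, 1, 3"), matching how
stability tables are printed.

### Consensus

Per gene, the geometric mean of its four per-method ranks; genes sort
ascending. GM ties are broken by mean rank then symbol so output is
deterministic. The consensus consumes this package's own four rankings
(auditable end-to-end) rather than re-deriving sub-rankings externally.

### Gene count

With genes ordered best-first by geNorm, `NF_n,s` is the geometric mean
quantity of the top n genes and `V_n = SD_s(log2 NF_n/NF_{n+1})`. The
first V below the 0.15 cutoff fixes the count; if none clears it the
smallest V wins (ties to smaller n). The NF correlation check (Pearson r
between NF₃ and NF at the chosen count) is computed on log2 NF — NF is a
geometric-mean quantity, so the log scale is natural — with the
linear-scale r reported alongside, since published figures rarely state
which was used. The pragmatic "three genes are usually enough" cap is a
report note, never enforced.

### Target-gene validation

`ΔCT_s = CT_target − mean(CT_refs)`; subtracting the calibrator-group mean
ΔCT and exponentiating gives 2^−ΔΔCT. The arithmetic mean of reference CTs
equals the geometric mean of their quantities at E = 2; an
efficiency-corrected mode is available. The calibrator defaults to the
first level in sorted-sample order and is always overridable. Group
differences: one-way ANOVA then Tukey HSD; the compact letter display is
built by insert-and-absorb (start with one letter set containing all
groups; for each significant pair split every set containing both, then
absorb subsets) and verified in tests by brute force against the pairwise
significance matrix. Both comparisons published figure legends use —
among groups within a normalizer, and among normalizers within a group —
are available, since normalizer disagreement is itself the signal of an
unstable reference.

## Synthetic data

The generator emulates the study designs the published tables come from:

    CT[i,(l,r,t)] = baseline_i + b_il + e_ilr + u_ilrt
    b_il ~ N(0, τ_i²)   per-level drift (instability)
    e    ~ N(0, σ_bio²) biological replicate noise
    u    ~ N(0, σ_tech²) technical replicate noise

Gaussian noise on the CT scale is the standard assumption (CT is log-scale
fluorescence). Defaults: baseline CTs at each gene's published mean CT
(10.7–25.9), published primer efficiencies, 3 biological × 3 technical
replicates, σ_bio = 0.3 and σ_tech = 0.15 cycles (typical bench
variability), and per-gene drift τ chosen to mirror the published
instability pattern: 18S 1.2, 28S 1.4, β-actin 0.8, TBP 0.6, the rest
0.15–0.35. Design presets carry the study's level counts
(8 developmental stages, 4 larval tissues, 6 adult tissues, 4 densities,
2 photoperiods, 2 temperatures).

"True stability" is defined as ascending `sqrt(τ² + σ_bio²)` — exactly the
dispersion the pairwise-SD methods estimate. Recovery tests plant one gene
with τ = 1.5 against an otherwise driftless panel (σ_bio = 0.3, 6 levels ×
3 reps) and require the consensus to rank it last in ≥ 95% of 200 seeded
runs; a pilot measured 200/200. A null calibration (all τ = 0) checks that
consensus positions are uniform across genes (pooled chi-square, pilot
p ≈ 0.38).

What the generator does **not** emulate: amplification-curve artefacts,
inhibition, batch/plate effects, non-Gaussian outliers, or correlated
regulation between candidate genes. Passing recovery tests therefore shows
the statistics behave correctly under the stated model, not that any
particular real panel is stable.

## Numerical choices and conventions

* All sample SDs use the n−1 divisor except the BestKeeper MAD.
* Stepwise geNorm worst-M ties: exclude the lexicographically last symbol.
* Negative variance estimates in NormFinder truncate at 0 (γ̂² likewise).
* BestKeeper correlations are undefined (reported NaN) for constant rows.
* NF correlation with zero-variance input is reported absent, not 0.
* Missing CT cells after technical-replicate collapse drop the gene for
  that condition set (no imputation — all four methods need complete
  matrices); the drop is logged.
* Pooled condition sets (all_biotic, all_abiotic, all_samples) concatenate
  member samples; group labels are qualified by condition set so NormFinder
  groups stay distinct.
* Problem sizes in the test suite (200-seed recovery loops, n = 1000
  NormFinder recovery, 100 random tables for the geNorm/ΔCT identity) were
  chosen to make the stochastic assertions stable while keeping the whole
  suite under a minute of compute.

## Embedded published tables

The per-method stability values and ranks for all nine condition sets are
embedded verbatim as worked-example inputs (`refstab.published`); the raw
CT data behind them were never deposited, so those printed tables — not
recomputation from raw data — are the reproducibility anchor. Re-ranking
each printed stability column finds a small number of printed rank entries
inconsistent with their own values (e.g. swapped ΔCT ranks for 18S/28S
under larval tissues, duplicated NormFinder rank 2 in the all-samples
table); they are kept as printed and excluded from rank-consistency
fixtures. Within these tables the geometric-mean consensus reproduces the
published comprehensive ordering in 7 of 9 condition sets exactly, and the
two exceptions trace precisely to those printing inconsistencies.

## Known limitations

* geNorm stepwise exclusion reports M at exclusion; full-panel M is also
  exposed but the two should not be mixed when comparing to other tools.
* NormFinder needs ≥ 3 genes (the bias corrector has k − 2 in the
  denominator) and ≥ 2 samples per group in grouped mode.
* The consensus treats the four methods as exchangeable; no weighting.
* Confidence intervals on stability values are out of scope.
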