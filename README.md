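# osteotx

Marker-gated transcriptomic analysis of osteoblasts under procollagen
misfolding stress — single-cell, spatial-spot, and bulk RNA-seq.

## The problem

Osteoblasts (OBs) devote up to ~40% of their mRNA to type I procollagen
(*Col1a1*/*Col1a2*). In osteogenesis imperfecta models such as the G610C
mouse, glycine substitutions make procollagen misfold and accumulate in
the ER, and OBs mount an integrated stress response (ISR) whose strength
tracks how much procollagen the cell is making. Detecting that
dose-dependent response from count data requires analysis choices that
tolerate a single gene dominating the library:

* **Relative counts, not log transforms.** Expression is kept as %UMI —
  a gene's UMI count as a percentage of the cell's total — with no log
  or variance-stabilizing transform and no scale factors.
* **Marker-threshold gating, not clustering.** OBs are selected by
  thresholds on *Col1a1*, *Runx2*, *Sp7* and *Ibsp* (with exclusion
  ceilings for contaminating cell types), not by UMAP/tSNE clusters.
* **UMI-weighted group means.** The mean expression of a gene in a
  group of cells is the pooled fraction
  `100 · Σ_c n_gc / Σ_c N_c` (gene counts over total counts), which
  weights every cell by its total UMI.
* **Rank tests with a change floor.** Group differences use the
  two-sided Wilcoxon rank-sum test, Bonferroni-corrected over the genes
  tested; a gene is called significant only when the weighted mean also
  changes by more than 20%.
* **Running averages along the Col1a1 gradient.** To see the dose
  response itself, cells are sorted by Col1a1 %UMI and a gene's pooled
  mean is computed over sliding 20-cell windows; genotype profiles are
  compared window-by-window, marking windows at p < 0.01 and reporting
  the expected false-positive count `n_windows × 0.01` instead of a
  Bonferroni correction.
* **Housekeeping RQ for bulk.** Bulk counts (no UMIs) are normalized to
  the geometric mean of four validated housekeeping genes (*Actg1*,
  *Actb*, *Mrfap1*, *Sdha*) per replicate — the sequencing analog of
  ΔΔCt — and tested with both Welch's t and Mann–Whitney U.

Every stage is backed by a synthetic-data generator
(`osteotx.simulate`) that reproduces the statistical structure of the
real data — a tri-modal Col1a1 gradient (early/differentiating/mature
OBs split at 0.75 and 3.5 %UMI), contaminant cell types with their
standard markers, genotype-scaled threshold dose responses,
negative-binomial counts, ~10-cell spatial spots, and bulk libraries —
with ground truth recorded per cell, so recovery can be tested without
any external download.

## Worked example

```python
import osteotx as ox

wt  = ox.simulate_cells(ox.SimulationSpec(n_cells=1500, genotype="WT",  seed=1, batch="wt0"))
het = ox.simulate_cells(ox.SimulationSpec(n_cells=1500, genotype="Het", seed=2, batch="het0"))
m, report = ox.filter_cells(ox.merge([wt, het]))

pct = ox.to_percent_umi(m)
selected, gating = ox.gate(pct, ox.GatingConfig(
    inclusion=[("Col1a1", 20.0), ("Runx2", 1.0), ("Sp7", 1.0), ("Ibsp", 1.0)],
    scale="count",
))
labels = ox.bin_subpopulations(pct, selected)   # eOB / dOB / mOB

meta = m.unit_meta.loc[selected]
mob = labels[labels == "mOB"].index
table = ox.differential_expression(
    m,
    [u for u in mob if meta.loc[u, "genotype"] == "WT"],
    [u for u in mob if meta.loc[u, "genotype"] == "Het"],
    genes=["Hspa9", "Atf5", "Eif4ebp1", "Hspa5", "Hsp90b1"],
    label_a="WT", label_b="Het",
)
print(table.round(4).to_string(index=False))
```

This prints (2758 of 3000 cells gated as OBs; 815 mOBs):

```
    gene  mean_WT  mean_Het  fold_change  pct_change  p_raw  p_adj  significant flag
   Hspa9   0.1002    0.1405       1.4028     40.2815 0.0000    0.0         True
    Atf5   0.0296    0.0446       1.5084     50.8385 0.0000    0.0         True
Eif4ebp1   0.0526    0.0708       1.3459     34.5904 0.0000    0.0         True
   Hspa5   0.3024    0.3034       1.0034      0.3394 0.8035    1.0        False
 Hsp90b1   0.1946    0.1955       1.0048      0.4833 0.8198    1.0        False
```

The ISR genes (*Hspa9*, *Atf5*, *Eif4ebp1*) come out upregulated in
mutant mature OBs while the ER-chaperone controls (*Hspa5*, *Hsp90b1*)
stay flat — the headline pattern the pipeline exists to detect. The
dose dependence itself is visible in the running-average comparison:

```python
cmp_ = ox.compare_profiles(
    m,
    [u for u in selected if meta.loc[u, "genotype"] == "WT"],
    [u for u in selected if meta.loc[u, "genotype"] == "Het"],
    "Hspa9",
)
```

which reports `157 of 1267 windows marked (expected false positives
12.7)`, with 140 of the marks above 3.5 %UMI Col1a1 — upregulation
confined to cells above the procollagen-load threshold.

A `osteotx` command-line tool wraps the same stages (`simulate`, `qc`,
`gate`, `trajectory`, `spatial`, `bulk`, `run-all`, `init-config`);
all thresholds live in a YAML config and can be overridden by flags.

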