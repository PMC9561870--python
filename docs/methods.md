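# Methods

This note records the models, defaults and numerical choices behind
`osteotx`, and what the synthetic tests do and do not establish about
real data.

## Expression statistics

All analysis operates on raw UMI counts. The only derived quantity is
the relative count, %UMI: `100 · n_gc / N_c` for gene *g* in unit *c*
(cell or spot) with total UMI `N_c`. No log transform, no
variance-stabilizing transform, no per-cell scale factors: when one
gene (Col1a1) can occupy tens of percent of the library, such
transforms distort exactly the signal of interest. Mitochondrial genes
are included in the denominator by default (`to_percent_umi` has a
flag to exclude them).

The group mean of a gene is the pooled fraction
`100 · Σ_c n_gc / Σ_c N_c`, equivalent to averaging per-cell %UMI with
each cell weighted by its total UMI. This differs from the unweighted
mean of per-cell %UMI whenever depth and expression covary; the test
suite asserts the weighted definition specifically.

## Quality control and gating

Cell filters: at least 500 detected genes (count > 0), no upper bound,
and mitochondrial fraction strictly below 10% (a cell at exactly 10%
is removed). Thresholds are deliberately permissive because osteoblasts
carry far more RNA than typical cells. Whole datasets are screened for
elevated cell-death markers (default Apaf1, Trp53inp1; user-extensible)
against a reference: per marker, a two-sided rank test on per-cell
%UMI, Bonferroni over the markers tested, discard when any marker is
significantly *elevated* (higher weighted mean, adjusted p below the
screen alpha; default 0.05). Datasets that pass are merged by gene
name with no batch correction or rescaling; duplicate barcodes get a
deterministic dataset-index suffix.

Osteoblasts are gated by inclusion thresholds on Col1a1, Runx2, Sp7
and Ibsp — raw UMI counts for cells, %UMI for spatial spots (the
config carries an explicit `scale` tag) — and, for spots, exclusion
ceilings Col2a1 < 0.15 %UMI and Col10a1 < 0.03 %UMI against
chondrocyte contamination. Threshold tuning is formalized as: over a
candidate grid, minimize the total number of selected units expressing
any exclusion marker (fibroblast Clec3b, endothelial Pecam1,
chondrocyte Acan, smooth-muscle Acta2, macrophage Cd68, Cd33) above a
cutoff (default: any positive expression), subject to retaining at
least `min_retention` of the units that co-express all four inclusion
markers; ties break toward the larger selected set, then the
lexicographically smallest thresholds. The objective is this package's
formalization of "exclude contaminants efficiently without losing
marker-positive cells" — the goal is standard, the exact function is a
design choice.

Selected cells are binned on Col1a1 %UMI at 0.75 and 3.5 into early
(eOB, < 0.75), differentiating (dOB, 0.75–3.5 inclusive at both
edges) and mature (mOB, > 3.5) subpopulations; edge values belong to
the middle bin.

## Differential expression

For each gene: pooled-fraction means in the two groups, fold change
B/A, percent change `|fold − 1| · 100`, a two-sided Wilcoxon rank-sum
p on the per-cell %UMI values, and Bonferroni adjustment with
denominator equal to the number of genes tested in the call (the
correction is applied when a gene list is being identified, not
genome-wide). Significance requires both more than 20% change and
adjusted p < 0.05; the 20% floor reflects the practical quantification
limit of scRNA-seq at these expression levels and is configurable.
Genes with zero counts in both groups are reported with p = 1 and a
flag, never dropped; a zero denominator makes the fold undefined
(flagged), and such genes can only be rated via an optional
pseudocount mode, off by default.

The rank test uses midranks with the tie variance correction; when
the smaller group has ≤ 8 observations and the data are untied it
switches to the exact permutation distribution (verified against
brute-force enumeration to 1e-12 in the tests). A degenerate input in
which every value is identical returns p = 1.

The cross-tissue gene filter retains genes that (i) are significant in
every required contrast (e.g. Hom-vs-WT mature OBs in embryonic bone
AND Het-vs-WT mature OBs in neonatal bone), (ii) change at least
two-fold, in either direction, in the designated contrast,
(iii) change in the same direction in each independent-experiment
table — direction agreement only, since a per-experiment significance
requirement is not part of the rule — and (iv) belong to at least two
functional categories of a user-supplied gene→category table (a
GO-style membership list; genes absent from the table count as zero
categories). Each gene carries a per-criterion pass/fail trace.

## Running-average trajectories

Cells are sorted by Col1a1 %UMI (ties broken by unit id, so profiles
are deterministic and independent of input order) and a gene is
summarized over windows of 20 consecutive cells at stride 1; the
window value is the pooled-fraction mean, the window covariate is the
simple mean of member cells' Col1a1 %UMI (monotone along stride-1
windows, which the alignment below relies on). Trailing cells that do
not fill a window are dropped.

To compare genotypes, each cohort's windows are paired by nearest
covariate (greedy in covariate order, each window of the second
cohort used at most once); a common-quantile-grid pairing is available
as an option. Each aligned pair is tested by the rank test on the two
windows' per-cell %UMI values (20 vs 20) — the only reading under
which a per-window two-sample test is computable. Windows with
p < 0.01 are marked. No correction is applied across windows;
instead the summary reports the expected false-positive count,
`n_windows × 0.01`, as the baseline against which a cluster of marks
should be read. With ~500 aligned windows that budget is ≤5 marks,
with ~1500 it is ≤15; because the rank test is discrete and slightly
conservative at n = 20, the realized null mean measured by
`scripts/acceptance.py` comes out near 4 and 13 respectively.
Overlapping windows make marks strongly correlated: a single local
fluctuation can mark dozens of consecutive windows, so per-replicate
counts are overdispersed and only the mean over many replicates is
meaningful.

Profile summaries (the "circle with error bar" statistic) report the
pooled mean over the cells of one Col1a1 bin together with the mean
over windows of the within-window standard deviation of per-cell %UMI
(population SD, so a single-cell window contributes 0 rather than an
undefined value).

## Bulk RQ normalization

Bulk libraries carry no UMIs and their size is dominated by the
genotype-dependent collagen fraction, so library-size normalizations
(FPKM/TPM/size factors) are not used. Instead each gene's count in a
replicate is divided by the geometric mean of the housekeeping-gene
counts in the same replicate (default panel Actg1, Actb, Mrfap1,
Sdha), the sequencing analog of ΔΔCt. The geometric mean is taken on
raw counts, matching the correspondence between Ct averages and count
geomeans; RQ is then exactly invariant to scaling a replicate's counts
by any constant. Housekeeping candidates are validated on single-cell
data by two criteria: stability (coefficient of variation of per-cell
%UMI pooled over genotypes, ceiling 1.0 by default) and genotype
neutrality (rank-test p above alpha). The published validation
procedure is not fully specified, so this CV + neutrality form is the
package's documented stand-in, with both knobs exposed.

Group comparisons run a two-sided Welch t-test and a Mann–Whitney U
test (exact where feasible). The significance call mirrors the
single-cell rule (> 20% mean change and t-test p < 0.05); a
discordance flag records when the two tests disagree at 0.05, the
situation annotated "#" in reports. Day-8 cultures (pre-steady-state)
are excluded by metadata, not hard-coded.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions used throughout the tests.

* **Counts.** Negative binomial in mean/dispersion form
  (var = μ + αμ²), sampled as gamma–Poisson. Per-cell-type dispersion
  defaults to α = 0.1, with per-gene overrides available. Library
  sizes are lognormal (median 9000 UMI, σ_log = 0.35) — osteoblasts
  are RNA-rich.
* **Col1a1 gradient.** A three-component lognormal mixture on the
  Col1a1 fraction with modes at 0.35, 1.7 and 7.5 %UMI (σ_log 0.35,
  0.28, 0.30), straddling the 0.75 and 3.5 gating edges. Component
  weights are genotype-dependent — WT (0.30, 0.40, 0.30),
  Het (0.33, 0.44, 0.23), Hom (0.36, 0.49, 0.15) — so the mature
  fraction shrinks with mutation load. Only the two edges are
  data-anchored; mode locations, widths and weights are free
  parameters chosen once to look like real histograms.
* **Dose response.** Stress-gene fractions are multiplied by a fold
  that is 1 below a Col1a1 threshold (default 3.5 %UMI), rises
  log-linearly in Col1a1 above it, and saturates at `max_fold` at
  `covariate_max` (default 15 %UMI). Genotype scales the response on
  the log-fold scale: WT = 0 (no response — WT stress expression is
  uncorrelated with Col1a1 by construction), Het = 0.6, Hom = 1. The
  fold is applied to each cell's *realized* Col1a1 %UMI (the Col1a1
  count is drawn first), so the response is as noisy as the covariate
  it follows. The default ISR panel (Hspa9, Atf5, Ddit3, Eif4ebp1,
  Nupr1, Trib3, Eif3c) responds; the ER-chaperone panel (Hspa5,
  Hsp90b1, Xbp1, Atf6) is flat in every genotype and serves as the
  negative control.
* **Cell types.** Osteoblasts plus fibroblast (Col1a1-low, Clec3b),
  endothelial (Pecam1), chondrocyte (Acan, Col2a1, trace Sp7),
  hypertrophic chondrocyte (Col10a1, trace Ibsp), smooth muscle
  (Acta2) and macrophage (Cd68, Cd33). Contaminants express stress,
  housekeeping and mitochondrial genes at the shared baseline but not
  the full OB marker combination — co-expression of all four OB
  markers is what gating exploits.
* **Budget closure.** Named-gene fractions are fixed; a panel of
  background genes (default 1200, long-tailed fixed weights) absorbs
  each cell's leftover budget, so stress-gene fractions do not drift
  with Col1a1 in WT.
* **QC exercise.** A configurable fraction of cells gets a tripled
  mitochondrial load (13 "mt-" genes, baseline 4.5% of UMI) or a
  collapsed library, to give the filters something to remove.
* **Spots.** Cells are pooled into spots of exactly `cells_per_spot`
  cells (default protocol ~10) on a coordinate grid; spot counts are
  exact sums of member-cell counts and the member list and cell-type
  tally are kept as ground truth.
* **Bulk.** Osteoblast profile with a fixed Col1a1 fraction (15%),
  lognormal library sizes (median 2×10⁶), and a between-replicate
  dispersion of 0.02 (~14% CV) — biological replicates of pooled
  culture wells, not single cells. Housekeeping genes cannot carry a
  genotype effect by construction.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the same spec and seed reproduce the same
matrix byte for byte. Not simulated: ambient RNA, doublets, read-level
error, cell-cycle structure, spatial autocorrelation beyond spot
pooling, and batch effects. Consequently the tests establish that the
pipeline recovers the structures it assumes (threshold dose responses,
marker-separable populations, stable housekeeping genes) at realistic
depths and noise levels — not that those assumptions hold in any
particular real dataset.

## Problem sizes and numerical conventions

The false-positive calibration (`scripts/acceptance.py` and the
corresponding test) uses cohorts of 525 and 1525 cells, giving ≈490
and ≈1470 aligned windows, with a 300-gene background panel — large
enough for the window protocol, small enough to average 400 replicate
simulations per size in about two minutes. Statistical tests in the
suite use 3σ binomial tolerances around nominal levels; exactness
checks (weighted means, rank-test enumeration, RQ scale invariance)
are asserted at 1e-12 relative. Ties in covariate sorting break by
unit id; bin edges belong to the interior bin; the Bonferroni
denominator is always the number of genes in the calling analysis;
fold changes with zero denominators are flagged rather than
pseudocounted unless the pseudocount mode is explicitly enabled.

## Known limitations

* Window pairing between genotypes is a formalization the figures do
  not fully specify; "nearest covariate" is the default and a quantile
  grid is the alternative. Marked-window counts can differ slightly
  between the two near sparse covariate regions.
* The housekeeping validation criteria stand in for a published
  procedure whose details are not available; the defaults are
  conservative but not canonical.
* The tuning objective for gating thresholds optimizes leakage against
  a retention floor; other trade-offs (e.g. cost-weighted) may suit
  other datasets.
* Spot gating inherits spot heterogeneity: a spot mixing OBs with one
  chondrocyte fails the exclusion ceilings, so gated spot sets are
  small and conservative by design.
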