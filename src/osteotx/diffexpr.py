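"""Differential expression with UMI-weighted means and rank tests.

Group means are pooled UMI fractions (see :mod:`osteotx.normalize`),
the test is a two-sided Wilcoxon rank-sum on per-unit %UMI values,
multiple testing is handled by Bonferroni over the genes tested in the
call, and the default significance rule requires both >20% change in
the weighted mean and adjusted p < 0.05 — a change-magnitude floor set
by the statistical power attainable at scRNA-seq expression levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import CountMatrix
from .normalize import to_percent_umi, weighted_group_means

__all__ = [
    "SignificanceRule",
    "CrossTissueFilterSpec",
    "rank_test",
    "differential_expression",
    "cross_tissue_filter",
]


def rank_test(values_a, values_b, axis: int | None = None):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Ties are handled by midranks with the usual variance correction;
    when the smaller group has <= 8 observations and there are no ties
    the exact permutation distribution is used, so small-sample p-values
    match brute-force enumeration.

    Degenerate inputs where every observation (across both groups) is
    identical return p = 1 — there is no evidence of any difference.

    With ``axis`` given, ``values_a`` and ``values_b`` are stacks of
    samples and a vector of p-values is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if axis is None:
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be nonempty")
        pooled = np.concatenate([a.ravel(), b.ravel()])
        if np.ptp(pooled) == 0:
            return 1.0
        res = st.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.pvalue)
    if a.shape[axis] == 0 or b.shape[axis] == 0:
        raise ValueError("both groups must be nonempty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = st.mannwhitneyu(
            a, b, alternative="two-sided", method="auto", axis=axis
        )
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied stacks yield nan from the tie-corrected normal approximation
    return np.where(np.isnan(p), 1.0, p)


@dataclass(frozen=True)
class SignificanceRule:
    """Joint change-magnitude and p-value significance call.

    significant <=> pct_change > min_pct_change AND p_adj < alpha.
    ``pseudocount`` (off by default) is added to both weighted means
    before the fold change so genes absent in one group can be rated;
    without it such genes are flagged and never called significant.
    """

    min_pct_change: float = 20.0
    alpha: float = 0.05
    pseudocount: float | None = None


def differential_expression(
    m: CountMatrix,
    units_a,
    units_b,
    genes=None,
    rule: SignificanceRule = SignificanceRule(),
    min_group_size: int = 3,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-gene weighted-mean comparison of group B versus group A.

    Returns a table with one row per tested gene: the two pooled
    %UMI means, fold change B/A, percent change ``|fold - 1| * 100``,
    raw and Bonferroni-adjusted p (denominator = number of genes tested
    in this call), the significance flag, and a status flag for genes
    whose fold change is undefined (zero denominator) or that have zero
    counts in both groups.
    """
    units_a, units_b = list(units_a), list(units_b)
    if len(units_a) < min_group_size or len(units_b) < min_group_size:
        raise ValueError(
            f"groups must have >= {min_group_size} units "
            f"(got {len(units_a)} and {len(units_b)})"
        )
    if genes is None:
        genes = list(m.gene_names)
    genes = list(genes)
    n_tested = len(genes)

    pct = to_percent_umi(m)
    ia = pct.unit_indices(units_a)
    ib = pct.unit_indices(units_b)
    mean_a = weighted_group_means(m, units_a, genes)
    mean_b = weighted_group_means(m, units_b, genes)

    rows = []
    for g, ma, mb in zip(genes, mean_a, mean_b):
        va = pct.gene_values(g)[ia]
        vb = pct.gene_values(g)[ib]
        flag = ""
        if ma == 0 and mb == 0:
            p_raw, fold, pct_change = 1.0, np.nan, np.nan
            flag = "zero_both"
        else:
            p_raw = rank_test(va, vb)
            if rule.pseudocount is not None:
                fold = (mb + rule.pseudocount) / (ma + rule.pseudocount)
                pct_change = abs(fold - 1.0) * 100.0
            elif ma == 0:
                fold, pct_change = np.nan, np.nan
                flag = "undefined_fold"
            else:
                fold = mb / ma
                pct_change = abs(fold - 1.0) * 100.0
        p_adj = min(1.0, p_raw * n_tested)
        significant = (
            not np.isnan(pct_change)
            and pct_change > rule.min_pct_change
            and p_adj < rule.alpha
        )
        rows.append(
            (g, ma, mb, fold, pct_change, p_raw, p_adj, significant, flag)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            f"mean_{label_a}",
            f"mean_{label_b}",
            "fold_change",
            "pct_change",
            "p_raw",
            "p_adj",
            "significant",
            "flag",
        ],
    )
    table.attrs["n_tested"] = n_tested
    table.attrs["labels"] = (label_a, label_b)
    return table


def _mean_cols(table: pd.DataFrame) -> tuple[str, str]:
    cols = [c for c in table.columns if c.startswith("mean_")]
    if len(cols) != 2:
        raise ValueError("DE table must carry exactly two mean_* columns")
    return cols[0], cols[1]


@dataclass
class CrossTissueFilterSpec:
    """Four-criterion cross-tissue gene filter.

    i.   significant in every table named in ``required_significant``;
    ii.  at least ``min_fold`` change (either direction) in
         ``min_fold_contrast``;
    iii. same-direction fold change in every table named in
         ``replication_contrasts``;
    iv.  membership in at least ``min_categories`` functional
         categories of ``annotation_table`` (gene -> set of category
         names; genes absent from the table have zero categories).
    """

    required_significant: list = field(default_factory=list)
    min_fold_contrast: str = ""
    min_fold: float = 2.0
    replication_contrasts: list = field(default_factory=list)
    annotation_table: dict = field(default_factory=dict)
    min_categories: int = 2


def cross_tissue_filter(
    tables: dict[str, pd.DataFrame], spec: CrossTissueFilterSpec
) -> tuple[list[str], pd.DataFrame]:
    """Apply the four-criterion filter; returns (gene list, trace).

    The trace has one row per gene with a pass/fail column per
    criterion, so a rejected gene shows exactly which rule it failed.
    """
    needed = set(spec.required_significant) | set(spec.replication_contrasts)
    if spec.min_fold_contrast:
        needed.add(spec.min_fold_contrast)
    missing = needed - set(tables)
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")

    indexed = {name: t.set_index("gene") for name, t in tables.items()}
    gene_sets = [set(t.index) for t in indexed.values()]
    genes = sorted(set.intersection(*gene_sets)) if gene_sets else []

    rows = []
    for g in genes:
        c1 = all(
            bool(indexed[name].loc[g, "significant"])
            for name in spec.required_significant
        )
        if spec.min_fold_contrast:
            f = indexed[spec.min_fold_contrast].loc[g, "fold_change"]
            c2 = (not np.isnan(f)) and (
                f >= spec.min_fold or f <= 1.0 / spec.min_fold
            )
        else:
            c2 = True
        folds = [
            indexed[name].loc[g, "fold_change"]
            for name in spec.replication_contrasts
        ]
        if folds:
            c3 = (not any(np.isnan(f) for f in folds)) and (
                all(f > 1 for f in folds) or all(f < 1 for f in folds)
            )
        else:
            c3 = True
        n_cat = len(spec.annotation_table.get(g, ()))
        c4 = n_cat >= spec.min_categories
        rows.append((g, c1, c2, c3, c4, n_cat, c1 and c2 and c3 and c4))
    trace = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "significant_in_required",
            "min_fold_met",
            "replicated_direction",
            "annotation_met",
            "n_categories",
            "passes",
        ],
    )
    selected = trace.loc[trace["passes"], "gene"].tolist()
    return selected, trace
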