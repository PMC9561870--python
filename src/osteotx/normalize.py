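"""Relative-count (%UMI) normalization and UMI-weighted group means.

These are the two expression statistics everything downstream consumes:

* per-unit relative expression, ``100 * count(g, u) / total(u)`` — the
  "RC" normalization, deliberately without log transforms or scale
  factors, because those distort the heavily skewed expression profile
  of collagen-producing osteoblasts;
* the pooled-fraction group mean, ``100 * sum_u count(g, u) / sum_u
  total(u)``, which is the mean of per-cell %UMI with each cell
  weighted by its total UMI (so deeply sequenced cells count more,
  matching the information they carry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import MITO_PREFIX, CountMatrix, PercentUMIMatrix

__all__ = ["GroupMean", "to_percent_umi", "weighted_group_mean", "weighted_group_means"]


@dataclass(frozen=True)
class GroupMean:
    """UMI-weighted mean expression of one gene in one group of units."""

    gene: str
    group: str
    weighted_mean: float  # %UMI
    n_units: int


def to_percent_umi(m: CountMatrix, include_mito: bool = True) -> PercentUMIMatrix:
    """Convert raw counts to percent-of-total-UMI per unit.

    Parameters
    ----------
    m
        Raw count matrix; every unit must have total UMI > 0
        (guaranteed after QC filtering).
    include_mito
        When False, mitochondrial genes ("mt-" prefix) are excluded
        from the per-unit denominator (values are still reported for
        all genes).  Default True: the denominator is the full total.

    Raises
    ------
    ValueError
        If any unit has a zero denominator; the error names the unit.
    """
    if include_mito:
        totals = m.totals().astype(float)
    else:
        keep = np.array([not g.startswith(MITO_PREFIX) for g in m.gene_names])
        totals = np.asarray(m.counts[keep].sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [m.unit_ids[i] for i in zero[:5]]
        raise ValueError(f"unit(s) with zero total UMI: {bad}")
    scale = sp.diags(100.0 / totals)
    values = (m.counts @ scale).tocsr()
    return PercentUMIMatrix(
        values=values,
        totals=totals,
        gene_names=list(m.gene_names),
        unit_ids=list(m.unit_ids),
        unit_meta=m.unit_meta,
    )


def weighted_group_mean(
    m: CountMatrix, units, gene: str, group: str = ""
) -> GroupMean:
    """Pooled-fraction mean of ``gene`` over ``units``.

    Returns ``100 * sum(counts of gene) / sum(total UMI)`` over the
    group — equivalent to weighting each unit's %UMI by its total UMI.
    """
    units = list(units)
    if not units:
        raise ValueError("unit list is empty")
    idx = m.unit_indices(units)
    gi = m.gene_index(gene)
    sub = m.counts[:, idx]
    num = sub[gi].sum()
    den = sub.sum()
    return GroupMean(
        gene=gene,
        group=group,
        weighted_mean=100.0 * float(num) / float(den),
        n_units=len(units),
    )


def weighted_group_means(m: CountMatrix, units, genes) -> np.ndarray:
    """Vectorized pooled-fraction means (%UMI) for several genes at once."""
    units = list(units)
    if not units:
        raise ValueError("unit list is empty")
    idx = m.unit_indices(units)
    sub = m.counts[:, idx]
    den = float(sub.sum())
    rows = [m.gene_index(g) for g in genes]
    num = np.asarray(sub[rows].sum(axis=1)).ravel().astype(float)
    return 100.0 * num / den
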