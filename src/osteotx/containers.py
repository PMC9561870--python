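"""Core in-memory containers for UMI count data.

The whole pipeline works on raw UMI counts stored genes x units
(units are cells or spatial spots).  Counts are never transformed;
the only derived representation is the relative-count (%UMI) matrix
produced by :mod:`osteotx.normalize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "PercentUMIMatrix"]

MITO_PREFIX = "mt-"


def _as_csr_int(counts) -> sp.csr_matrix:
    m = sp.csr_matrix(counts)
    if m.nnz:
        data = m.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
            m = m.astype(np.int64)
        if m.data.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
    m = m.astype(np.int64)
    m.sum_duplicates()
    return m


@dataclass
class CountMatrix:
    """Sparse integer UMI counts, genes x units, with per-unit metadata.

    Parameters
    ----------
    counts
        Sparse (or dense, coerced) non-negative integer matrix,
        genes in rows and units (cells/spots) in columns.
    gene_names
        Unique gene symbols, one per row.
    unit_ids
        Unique unit identifiers (cell barcodes / spot ids), one per column.
    unit_meta
        Optional per-unit table (genotype, tissue, batch, x/y, ...).
        Indexed by ``unit_ids``; created empty when omitted.
    """

    counts: sp.csr_matrix
    gene_names: list[str]
    unit_ids: list[str]
    unit_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = _as_csr_int(self.counts)
        self.gene_names = list(map(str, self.gene_names))
        self.unit_ids = list(map(str, self.unit_ids))
        n_genes, n_units = self.counts.shape
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n_genes} rows"
            )
        if len(self.unit_ids) != n_units:
            raise ValueError(
                f"{len(self.unit_ids)} unit ids for {n_units} columns"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if len(set(self.unit_ids)) != n_units:
            raise ValueError("unit ids must be unique")
        if self.unit_meta is None:
            self.unit_meta = pd.DataFrame(index=pd.Index(self.unit_ids))
        else:
            self.unit_meta = pd.DataFrame(self.unit_meta)
            if len(self.unit_meta) != n_units:
                raise ValueError("unit_meta row count != number of units")
            self.unit_meta.index = pd.Index(self.unit_ids)

    # -- basic properties -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Total UMI per unit (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def features_per_unit(self) -> np.ndarray:
        """Number of detected genes (count > 0) per unit."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        """Per-unit fraction of UMI on mitochondrial genes (name prefix)."""
        mito = np.array([g.startswith(prefix) for g in self.gene_names])
        tot = self.totals().astype(float)
        if not mito.any():
            return np.zeros(self.n_units)
        mito_sum = np.asarray(self.counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito_sum / tot, 0.0)
        return frac

    # -- indexing ---------------------------------------------------------

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def unit_indices(self, unit_ids) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            return np.array([lookup[u] for u in unit_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unit {e.args[0]!r} not in matrix") from None

    def gene_counts(self, gene: str, unit_ids=None) -> np.ndarray:
        """Dense count vector for one gene over (a subset of) units."""
        row = np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()
        if unit_ids is not None:
            row = row[self.unit_indices(unit_ids)]
        return row

    def subset_units(self, unit_ids) -> "CountMatrix":
        idx = self.unit_indices(unit_ids)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_names,
            [self.unit_ids[i] for i in idx],
            self.unit_meta.iloc[idx].copy(),
        )

    def subset_genes(self, gene_names) -> "CountMatrix":
        idx = [self.gene_index(g) for g in gene_names]
        return CountMatrix(
            self.counts[idx, :],
            [self.gene_names[i] for i in idx],
            self.unit_ids,
            self.unit_meta.copy(),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(),
            list(self.gene_names),
            list(self.unit_ids),
            self.unit_meta.copy(),
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_names == other.gene_names
            and self.unit_ids == other.unit_ids
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class PercentUMIMatrix:
    """Relative expression: each gene as percent of the unit's total UMI.

    ``values[g, u] = 100 * counts[g, u] / totals[u]`` — no log, no scale
    factors.  Column sums are 100 by construction (when the denominator
    includes all genes).
    """

    values: sp.csr_matrix
    totals: np.ndarray
    gene_names: list[str]
    unit_ids: list[str]
    unit_meta: pd.DataFrame

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def unit_indices(self, unit_ids) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            return np.array([lookup[u] for u in unit_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unit {e.args[0]!r} not in matrix") from None

    def gene_values(self, gene: str, unit_ids=None) -> np.ndarray:
        """Dense %UMI vector for one gene over (a subset of) units."""
        row = np.asarray(self.values[self.gene_index(gene)].todense()).ravel()
        if unit_ids is not None:
            row = row[self.unit_indices(unit_ids)]
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values.todense()),
            index=self.gene_names,
            columns=self.unit_ids,
        )
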