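"""Reading/writing count matrices and quality-control filtering.

Matrices travel as 10x-style triplet directories: ``matrix.mtx``
(MatrixMarket coordinate format, genes x units), ``genes.tsv``,
``barcodes.tsv``, and a ``metadata.tsv`` carrying the per-unit table.
Spot coordinates, when present in the metadata, are additionally
written as ``spot_positions.tsv``.

QC keeps the filters deliberately permissive for osteoblasts, which
produce far more RNA than most cells: at least 500 detected genes per
cell, no upper feature bound, and strictly less than 10% mitochondrial
UMI.  Whole datasets are additionally screened for elevated cell-death
markers (Apaf1, Trp53inp1, ...) against a reference and discarded
outright when a marker is significantly up.  Datasets that pass are
merged without any batch correction or rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import MITO_PREFIX, CountMatrix
from .diffexpr import rank_test
from .normalize import to_percent_umi, weighted_group_mean

__all__ = [
    "QCConfig",
    "QCReport",
    "DeathScreenResult",
    "read_matrix",
    "write_matrix",
    "filter_cells",
    "screen_dataset_death_markers",
    "merge",
]

DEFAULT_DEATH_MARKERS = ["Apaf1", "Trp53inp1"]


@dataclass
class QCConfig:
    """Cell-level and dataset-level quality-control thresholds."""

    min_features: int = 500
    max_features: int | None = None
    max_mito_fraction: float = 0.10
    death_markers: list[str] = field(
        default_factory=lambda: list(DEFAULT_DEATH_MARKERS)
    )
    death_screen_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")


@dataclass(frozen=True)
class QCReport:
    n_in: int
    n_kept: int
    n_low_features: int
    n_high_features: int
    n_high_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def write_matrix(m: CountMatrix, path) -> None:
    """Write a triplet directory (MTX + genes + barcodes + metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", m.counts.tocoo(), field="integer")
    pd.DataFrame({"gene_id": m.gene_names, "gene_name": m.gene_names}).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.unit_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = m.unit_meta.copy()
    meta.insert(0, "unit_id", m.unit_ids)
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
    if {"row", "col", "x", "y"} <= set(m.unit_meta.columns):
        pos = m.unit_meta[["row", "col", "x", "y"]].copy()
        pos.insert(0, "spot_id", m.unit_ids)
        pos.to_csv(path / "spot_positions.tsv", sep="\t", index=False)


def read_matrix(path) -> CountMatrix:
    """Read a triplet directory written by :func:`write_matrix`.

    Duplicate entries at the same coordinate are summed (MatrixMarket
    coordinate-format convention).  Dimension mismatches between the
    MTX header and the name files are format errors, as is an empty
    barcode file.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx in {path}")
    counts = sp.csr_matrix(scipy.io.mmread(mtx))  # tocsr sums duplicates
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
    gene_names = genes.iloc[:, -1].astype(str).tolist()
    bc_path = path / "barcodes.tsv"
    if bc_path.stat().st_size == 0:
        raise ValueError(f"empty barcode file: {bc_path}")
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    if counts.shape != (len(gene_names), len(barcodes)):
        raise ValueError(
            f"matrix is {counts.shape} but name files give "
            f"({len(gene_names)}, {len(barcodes)})"
        )
    meta_path = path / "metadata.tsv"
    meta = None
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        meta = meta.drop(columns=["unit_id"], errors="ignore")
    return CountMatrix(counts, gene_names, barcodes, meta)


def filter_cells(m: CountMatrix, qc: QCConfig = QCConfig()) -> tuple[CountMatrix, QCReport]:
    """Apply per-cell feature and mitochondrial-fraction filters.

    A unit is kept when its detected-gene count is >= ``min_features``
    (and <= ``max_features`` if set) and its mitochondrial UMI fraction
    is strictly below ``max_mito_fraction`` (a cell at exactly the
    bound is removed).  The report counts removals per criterion; a
    cell can fail more than one.
    """
    feats = m.features_per_unit()
    mito = m.mito_fraction(MITO_PREFIX)
    low = feats < qc.min_features
    high = (
        feats > qc.max_features
        if qc.max_features is not None
        else np.zeros_like(low)
    )
    mito_bad = mito >= qc.max_mito_fraction
    keep = ~(low | high | mito_bad)
    report = QCReport(
        n_in=m.n_units,
        n_kept=int(keep.sum()),
        n_low_features=int(low.sum()),
        n_high_features=int(high.sum()),
        n_high_mito=int(mito_bad.sum()),
    )
    if report.n_kept == 0:
        warnings.warn(
            "QC removed every unit; returning an empty matrix", UserWarning
        )
    kept_ids = [u for u, k in zip(m.unit_ids, keep) if k]
    return m.subset_units(kept_ids), report


@dataclass
class DeathScreenResult:
    discard: bool
    table: pd.DataFrame  # per-marker means, p-values, flags
    untested: list[str]


def screen_dataset_death_markers(
    m: CountMatrix, reference: CountMatrix, qc: QCConfig = QCConfig()
) -> DeathScreenResult:
    """Compare cell-death-marker expression against a reference dataset.

    Per marker: the UMI-weighted mean in each dataset and a two-sided
    rank test on per-cell %UMI, Bonferroni-corrected over the markers
    tested.  The dataset is flagged for discard when any marker is
    significantly *elevated* (higher weighted mean and adjusted
    p < ``death_screen_alpha``).  Markers absent from either gene
    universe are listed as untested, not treated as failures.
    """
    markers = list(qc.death_markers)
    testable = [
        g for g in markers if g in m.gene_names and g in reference.gene_names
    ]
    untested = [g for g in markers if g not in testable]
    n_tested = len(testable)
    pct_m = to_percent_umi(m)
    pct_r = to_percent_umi(reference)
    rows = []
    discard = False
    for g in testable:
        mean_test = weighted_group_mean(m, m.unit_ids, g).weighted_mean
        mean_ref = weighted_group_mean(
            reference, reference.unit_ids, g
        ).weighted_mean
        p_raw = rank_test(pct_m.gene_values(g), pct_r.gene_values(g))
        p_adj = min(1.0, p_raw * n_tested)
        elevated = mean_test > mean_ref and p_adj < qc.death_screen_alpha
        discard = discard or elevated
        rows.append((g, mean_test, mean_ref, p_raw, p_adj, elevated))
    table = pd.DataFrame(
        rows,
        columns=["marker", "mean_test", "mean_reference", "p_raw", "p_adj", "elevated"],
    )
    return DeathScreenResult(discard=discard, table=table, untested=untested)


def merge(datasets: list[CountMatrix]) -> CountMatrix:
    """Concatenate datasets unit-wise with no transformation.

    Genes are aligned by name.  Identical universes concatenate
    losslessly; otherwise the intersection is used with a warning.
    Duplicate unit ids across datasets get a deterministic ``-<k>``
    suffix (dataset position).
    """
    if not datasets:
        raise ValueError("nothing to merge")
    if len(datasets) == 1:
        return datasets[0].copy()
    gene_sets = [list(d.gene_names) for d in datasets]
    if all(g == gene_sets[0] for g in gene_sets[1:]):
        genes = gene_sets[0]
        aligned = datasets
    else:
        common = set(gene_sets[0])
        for g in gene_sets[1:]:
            common &= set(g)
        if not common:
            raise ValueError("datasets share no genes")
        genes = [g for g in gene_sets[0] if g in common]
        dropped = sum(len(gs) - len(genes) for gs in gene_sets)
        if dropped:
            warnings.warn(
                f"merging on {len(genes)} shared genes (gene universes differ)",
                UserWarning,
            )
        aligned = [d.subset_genes(genes) for d in datasets]

    seen: set[str] = set()
    all_ids: list[str] = []
    metas = []
    for k, d in enumerate(aligned):
        for u in d.unit_ids:
            uid = u if u not in seen else f"{u}-{k}"
            seen.add(uid)
            all_ids.append(uid)
        metas.append(d.unit_meta)
    counts = sp.hstack([d.counts for d in aligned]).tocsr()
    meta = pd.concat(metas, axis=0, ignore_index=True)
    return CountMatrix(counts, genes, all_ids, meta)
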