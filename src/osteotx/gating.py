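"""Marker-threshold gating of osteoblasts and osteoblast-enriched spots.

Osteoblasts are selected operationally — above-threshold expression of
the marker genes Col1a1, Runx2, Sp7 and Ibsp — rather than by
unsupervised clustering, which misplaces cells when the target
population is already well characterized by markers.  Spatial spots
additionally carry exclusion ceilings (Col2a1 < 0.15 %UMI,
Col10a1 < 0.03 %UMI) to reject chondrocyte contamination.

The module also tunes inclusion thresholds against contaminating cell
types (fibroblast Clec3b, endothelial Pecam1, chondrocyte Acan, smooth
muscle Acta2, macrophage Cd68, neutrophil/macrophage Cd33) and bins
selected cells into early / differentiating / mature subpopulations by
Col1a1 %UMI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PercentUMIMatrix

__all__ = [
    "GatingConfig",
    "GatingReport",
    "SubpopulationBins",
    "gate",
    "tune_thresholds",
    "bin_subpopulations",
]

OB_MARKERS = ["Col1a1", "Runx2", "Sp7", "Ibsp"]
CONTAMINANT_MARKERS = ["Clec3b", "Pecam1", "Acan", "Acta2", "Cd68", "Cd33"]
SPOT_EXCLUSION = [("Col2a1", 0.15), ("Col10a1", 0.03)]


@dataclass
class GatingConfig:
    """Inclusion/exclusion marker thresholds.

    ``inclusion``: list of (gene, minimum) — a unit must reach every
    minimum.  ``scale`` says whether inclusion minima are raw UMI
    counts ("count", the cell-gating convention) or %UMI ("percent",
    the spot convention).  ``exclusion``: list of (gene, ceiling),
    always in %UMI; a unit must stay strictly below every ceiling.
    """

    inclusion: list[tuple[str, float]]
    exclusion: list[tuple[str, float]] = field(default_factory=list)
    mode: str = "cell"  # {"cell", "spot"} — bookkeeping label
    scale: str = "count"  # {"count", "percent"} for inclusion minima

    def __post_init__(self) -> None:
        if not self.inclusion:
            raise ValueError("inclusion list must be nonempty")
        for g, t in list(self.inclusion) + list(self.exclusion):
            if t < 0:
                raise ValueError(f"negative threshold for {g}")
        if self.scale not in ("count", "percent"):
            raise ValueError("scale must be 'count' or 'percent'")

    def to_dict(self) -> dict:
        return {
            "inclusion": [[g, float(t)] for g, t in self.inclusion],
            "exclusion": [[g, float(t)] for g, t in self.exclusion],
            "mode": self.mode,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingConfig":
        return cls(
            inclusion=[(g, float(t)) for g, t in d["inclusion"]],
            exclusion=[(g, float(t)) for g, t in d.get("exclusion", [])],
            mode=d.get("mode", "cell"),
            scale=d.get("scale", "count"),
        )


@dataclass(frozen=True)
class GatingReport:
    n_in: int
    n_selected: int
    # fraction of *selected* units above the reporting cutoff, per marker
    leakage: dict[str, float]


def _inclusion_values(m: PercentUMIMatrix, gene: str, scale: str) -> np.ndarray:
    vals = m.gene_values(gene)
    if scale == "count":
        # raw counts are recoverable from %UMI and the stored totals
        return vals * m.totals / 100.0
    return vals


def gate(
    m: PercentUMIMatrix,
    cfg: GatingConfig,
    report_markers: dict[str, float] | None = None,
) -> tuple[list[str], GatingReport]:
    """Select units meeting all inclusion minima and exclusion ceilings.

    A unit is selected iff value >= minimum for every inclusion marker
    (on the configured scale) AND %UMI < ceiling for every exclusion
    marker.  ``report_markers`` (gene -> %UMI cutoff) adds diagnostic
    leakage fractions for markers that are not part of the gate.
    """
    missing = [
        g
        for g, _ in list(cfg.inclusion) + list(cfg.exclusion)
        if g not in m.gene_names
    ]
    if missing:
        raise KeyError(f"gating genes absent from matrix: {missing}")

    keep = np.ones(m.n_units, dtype=bool)
    for g, t in cfg.inclusion:
        keep &= _inclusion_values(m, g, cfg.scale) >= t
    for g, c in cfg.exclusion:
        keep &= m.gene_values(g) < c

    selected = [u for u, k in zip(m.unit_ids, keep) if k]
    leakage: dict[str, float] = {}
    cutoffs = {g: c for g, c in cfg.exclusion}
    if report_markers:
        cutoffs.update(report_markers)
    n_sel = int(keep.sum())
    for g, c in cutoffs.items():
        if g not in m.gene_names:
            continue
        if n_sel == 0:
            leakage[g] = 0.0
        else:
            leakage[g] = float((m.gene_values(g)[keep] >= c).mean())
    return selected, GatingReport(n_in=m.n_units, n_selected=n_sel, leakage=leakage)


def tune_thresholds(
    m: PercentUMIMatrix,
    inclusion_genes: list[str],
    exclusion_genes: list[str],
    grid: dict[str, list[float]] | list[tuple[float, ...]],
    min_retention: float,
    scale: str = "count",
    leakage_cutoff: float = 0.0,
) -> tuple[GatingConfig, pd.DataFrame]:
    """Pick inclusion thresholds that best exclude contaminating cells.

    The candidate set is the cartesian product of per-gene threshold
    lists (or an explicit list of threshold tuples).  The retained
    reference population is the units co-expressing *all* inclusion
    markers at any positive level.  Among candidates that keep at
    least ``min_retention`` of that population, the one minimizing the
    total exclusion-marker leakage (number of selected units with an
    exclusion marker above ``leakage_cutoff`` %UMI, summed over
    markers) wins; ties break toward the larger selected set, then the
    lexicographically smallest threshold tuple.
    """
    if not 0 < min_retention <= 1:
        raise ValueError("min_retention must be in (0, 1]")
    if isinstance(grid, dict):
        genes = list(inclusion_genes)
        candidates = list(itertools.product(*(grid[g] for g in genes)))
    else:
        genes = list(inclusion_genes)
        candidates = [tuple(c) for c in grid]
    if not candidates:
        raise ValueError("threshold grid is empty")

    inc_vals = np.vstack([_inclusion_values(m, g, scale) for g in genes])
    exc_pos = np.vstack(
        [m.gene_values(g) > leakage_cutoff for g in exclusion_genes]
    ) if exclusion_genes else np.zeros((0, m.n_units), dtype=bool)

    coexpressing = (inc_vals > 0).all(axis=0)
    n_ref = int(coexpressing.sum())
    if n_ref == 0:
        raise ValueError("no unit co-expresses all inclusion markers")

    rows = []
    for cand in candidates:
        sel = (inc_vals >= np.asarray(cand)[:, None]).all(axis=0)
        retention = float((sel & coexpressing).sum()) / n_ref
        leak = int(exc_pos[:, sel].sum()) if exc_pos.size else 0
        rows.append(
            {
                "thresholds": cand,
                "n_selected": int(sel.sum()),
                "retention": retention,
                "total_leakage": leak,
            }
        )
    diag = pd.DataFrame(rows)
    ok = diag[diag["retention"] >= min_retention]
    if ok.empty:
        best = diag.sort_values("retention", ascending=False).head(5)
        raise ValueError(
            "no grid point meets the retention floor "
            f"{min_retention}; best candidates:\n{best}"
        )
    ranked = sorted(
        ok.itertuples(index=False),
        key=lambda r: (r.total_leakage, -r.n_selected, r.thresholds),
    )
    winner = ranked[0]
    cfg = GatingConfig(
        inclusion=list(zip(genes, winner.thresholds)),
        exclusion=[],
        mode="cell",
        scale=scale,
    )
    return cfg, diag


@dataclass
class SubpopulationBins:
    """Ordered %UMI cut points partitioning a marker gradient.

    Defaults reproduce the tri-modal Col1a1 structure of the osteoblast
    lineage: early (< 0.75 %UMI), differentiating (0.75–3.5, closed at
    both edges), mature (> 3.5).
    """

    gene: str = "Col1a1"
    edges: tuple[float, ...] = (0.75, 3.5)
    labels: tuple[str, ...] = ("eOB", "dOB", "mOB")

    def __post_init__(self) -> None:
        edges = tuple(self.edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if len(self.labels) != len(edges) + 1:
            raise ValueError("need exactly len(edges)+1 labels")
        self.edges = edges
        self.labels = tuple(self.labels)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; edge values fall in the interior bin.

        Lower bin is strict (< first edge), interior bins are closed at
        both edges, upper bin is strict (> last edge); a value equal to
        an interior-shared edge goes to the lower of the two bins.
        """
        v = np.asarray(values, dtype=float)
        edges = np.asarray(self.edges)
        idx = np.searchsorted(edges, v, side="right")
        if len(edges) > 1:
            on_upper = np.isin(v, edges[1:])
            idx = idx - on_upper.astype(int)
        return idx


def bin_subpopulations(
    m: PercentUMIMatrix, selected, bins: SubpopulationBins = SubpopulationBins()
) -> pd.Series:
    """Label each selected unit by its bin of the gradient gene."""
    selected = list(selected)
    vals = m.gene_values(bins.gene, selected)
    idx = bins.assign(vals)
    return pd.Series(
        [bins.labels[i] for i in idx], index=selected, name=f"{bins.gene}_bin"
    )
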