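"""Covariate-sorted running-average expression profiles.

Cells are sorted by the %UMI of a covariate gene (Col1a1 — a proxy for
procollagen synthesis load) and a gene's expression is summarized over
consecutive windows of ``window_size`` cells as the pooled UMI
fraction.  Profiles of two genotypes are compared window-by-window
with a rank test; instead of a Bonferroni correction (which would
drown real dose-response signal), a strict mark threshold (p < 0.01)
is used and the expected number of false positives — n_windows x
alpha — is reported alongside, so a cluster of marked windows above a
covariate threshold can be read against that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .containers import CountMatrix
from .diffexpr import rank_test
from .gating import SubpopulationBins
from .normalize import to_percent_umi

__all__ = [
    "TrajectoryProfile",
    "ProfileComparison",
    "build_profile",
    "compare_profiles",
    "summarize_profile_mean",
]


@dataclass
class TrajectoryProfile:
    """Running-average profile of one gene along a covariate gradient.

    Cells appear in covariate order (ties broken by unit id); window i
    covers sorted cells ``starts[i] .. starts[i] + window_size``.  The
    per-window value is the pooled-fraction mean (sum of gene counts
    over sum of totals, x100); the per-window covariate is the simple
    mean of the member cells' covariate %UMI, which is monotone along
    stride-1 windows and is what the profiles are aligned on.
    """

    gene: str
    covariate: str
    window_size: int
    stride: int
    sorted_units: list[str]
    cell_covariate: np.ndarray  # %UMI, sorted ascending
    cell_values: np.ndarray  # per-cell gene %UMI in the same order
    cell_gene_counts: np.ndarray
    cell_totals: np.ndarray
    starts: np.ndarray
    window_covariate: np.ndarray
    window_covariate_max: np.ndarray
    window_value: np.ndarray  # pooled-fraction %UMI per window

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def window_members(self, i: int) -> list[str]:
        s = int(self.starts[i])
        return self.sorted_units[s : s + self.window_size]

    def window_cell_values(self, i: int) -> np.ndarray:
        s = int(self.starts[i])
        return self.cell_values[s : s + self.window_size]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": np.arange(self.n_windows),
                "covariate_mean": self.window_covariate,
                "value": self.window_value,
            }
        )


def build_profile(
    m: CountMatrix,
    units,
    gene: str,
    covariate: str = "Col1a1",
    window_size: int = 20,
    stride: int = 1,
) -> TrajectoryProfile:
    """Sort ``units`` by covariate %UMI and slide a pooled-mean window.

    Trailing cells that do not fill a complete window are dropped.
    Sorting is deterministic: ties on the covariate break by unit id.
    """
    units = list(units)
    if window_size < 1 or stride < 1:
        raise ValueError("window_size and stride must be >= 1")
    if len(units) < window_size:
        raise ValueError(
            f"window_size {window_size} exceeds {len(units)} units"
        )
    sub = m.subset_units(units)
    pct = to_percent_umi(sub)
    cov = pct.gene_values(covariate)
    val = pct.gene_values(gene)
    counts = sub.gene_counts(gene)
    totals = sub.totals().astype(float)

    order = sorted(range(len(units)), key=lambda i: (cov[i], sub.unit_ids[i]))
    order = np.asarray(order, dtype=np.intp)
    cov, val = cov[order], val[order]
    counts, totals = counts[order].astype(float), totals[order]
    sorted_units = [sub.unit_ids[i] for i in order]

    starts = np.arange(0, len(units) - window_size + 1, stride)
    win_counts = sliding_window_view(counts, window_size)[starts]
    win_totals = sliding_window_view(totals, window_size)[starts]
    win_cov = sliding_window_view(cov, window_size)[starts]
    window_value = 100.0 * win_counts.sum(axis=1) / win_totals.sum(axis=1)
    window_covariate = win_cov.mean(axis=1)
    window_covariate_max = win_cov.max(axis=1)

    return TrajectoryProfile(
        gene=gene,
        covariate=covariate,
        window_size=window_size,
        stride=stride,
        sorted_units=sorted_units,
        cell_covariate=cov,
        cell_values=val,
        cell_gene_counts=counts,
        cell_totals=totals,
        starts=starts,
        window_covariate=window_covariate,
        window_covariate_max=window_covariate_max,
        window_value=window_value,
    )


@dataclass
class ProfileComparison:
    """Aligned window-by-window comparison of two genotype profiles."""

    gene: str
    covariate: str
    alpha_mark: float
    table: pd.DataFrame  # window pairs with p values and mark flags
    n_windows: int
    expected_fp: float

    @property
    def n_marked(self) -> int:
        return int(self.table["marked"].sum())


def _pair_windows_nearest(cov_a: np.ndarray, cov_b: np.ndarray) -> list[tuple[int, int]]:
    """Greedy nearest-covariate pairing, each B window used at most once.

    Both arrays are monotone nondecreasing, so a single forward sweep
    suffices: for each A window in order, advance the B pointer while
    the next unused B window is at least as close.
    """
    pairs = []
    j = 0
    for i in range(len(cov_a)):
        if j >= len(cov_b):
            break
        while j + 1 < len(cov_b) and abs(cov_b[j + 1] - cov_a[i]) <= abs(
            cov_b[j] - cov_a[i]
        ):
            j += 1
        pairs.append((i, j))
        j += 1
    return pairs


def _pair_windows_quantile(cov_a: np.ndarray, cov_b: np.ndarray) -> list[tuple[int, int]]:
    """Pair windows on a common quantile grid of their own orderings."""
    n = min(len(cov_a), len(cov_b))
    ia = np.round(np.linspace(0, len(cov_a) - 1, n)).astype(int)
    ib = np.round(np.linspace(0, len(cov_b) - 1, n)).astype(int)
    return list(zip(ia, ib))


def compare_profiles(
    m: CountMatrix,
    units_a,
    units_b,
    gene: str,
    covariate: str = "Col1a1",
    window_size: int = 20,
    alpha_mark: float = 0.01,
    stride: int = 1,
    pairing: str = "nearest",
) -> ProfileComparison:
    """Per-window rank tests between two cohorts' running averages.

    Each aligned window pair is tested by comparing the two windows'
    per-cell %UMI values of ``gene`` (window_size vs window_size
    observations).  Windows with p < ``alpha_mark`` are marked; the
    summary carries ``expected_fp = n_windows * alpha_mark`` as the
    false-positive baseline.
    """
    prof_a = build_profile(m, units_a, gene, covariate, window_size, stride)
    prof_b = build_profile(m, units_b, gene, covariate, window_size, stride)
    if pairing == "nearest":
        pairs = _pair_windows_nearest(prof_a.window_covariate, prof_b.window_covariate)
    elif pairing == "quantile":
        pairs = _pair_windows_quantile(prof_a.window_covariate, prof_b.window_covariate)
    else:
        raise ValueError("pairing must be 'nearest' or 'quantile'")
    if len(pairs) < 2:
        raise ValueError(f"only {len(pairs)} aligned windows; need >= 2")

    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    wa = sliding_window_view(prof_a.cell_values, window_size)[prof_a.starts][ia]
    wb = sliding_window_view(prof_b.cell_values, window_size)[prof_b.starts][ib]
    pvals = rank_test(wa, wb, axis=1)
    marked = pvals < alpha_mark

    table = pd.DataFrame(
        {
            "window": np.arange(len(pairs)),
            "window_A": ia,
            "window_B": ib,
            "covariate_A": prof_a.window_covariate[ia],
            "covariate_B": prof_b.window_covariate[ib],
            "covariate_max_A": prof_a.window_covariate_max[ia],
            "covariate_max_B": prof_b.window_covariate_max[ib],
            "value_A": prof_a.window_value[ia],
            "value_B": prof_b.window_value[ib],
            "p_raw": pvals,
            "marked": marked,
        }
    )
    return ProfileComparison(
        gene=gene,
        covariate=covariate,
        alpha_mark=alpha_mark,
        table=table,
        n_windows=len(pairs),
        expected_fp=len(pairs) * alpha_mark,
    )


def summarize_profile_mean(
    profile: TrajectoryProfile,
    bins: SubpopulationBins = SubpopulationBins(),
    label: str = "mOB",
) -> tuple[float, float]:
    """Weighted mean in one covariate bin and mean running-window SD.

    Returns ``(mean, dispersion)``: the pooled-fraction mean of the
    profiled gene over the cells whose covariate falls in ``label``'s
    bin, and the mean across all windows of the per-window standard
    deviation of per-cell %UMI (population SD, so a single-cell window
    contributes 0 rather than an undefined value).
    """
    if label not in bins.labels:
        raise ValueError(f"unknown bin label {label!r}")
    want = bins.labels.index(label)
    idx = bins.assign(profile.cell_covariate) == want
    if not idx.any():
        raise ValueError(f"no profiled cells fall in bin {label!r}")
    mean = (
        100.0
        * profile.cell_gene_counts[idx].sum()
        / profile.cell_totals[idx].sum()
    )
    win_vals = sliding_window_view(profile.cell_values, profile.window_size)[
        profile.starts
    ]
    dispersion = float(win_vals.std(axis=1).mean())
    return float(mean), dispersion
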