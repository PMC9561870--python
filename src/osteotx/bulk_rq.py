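"""Housekeeping-gene relative-quantity (RQ) normalization of bulk counts.

Bulk RNA-seq of cultured osteoblasts cannot use %UMI (no UMIs) and the
usual library-size normalizations are distorted by the enormous,
genotype-dependent collagen fraction.  Instead each gene's count in a
replicate is divided by the geometric mean of the housekeeping-gene
counts in the same replicate — the sequencing analog of the ddCt
approach in qPCR.  RQ is exactly invariant to per-replicate scaling.

Housekeeping candidates (default Actg1, Actb, Mrfap1, Sdha) are
validated against single-cell data: stable (%UMI coefficient of
variation under a ceiling) and genotype-neutral (rank test above
alpha).  Group comparisons run both a Welch t-test and a Mann-Whitney
U-test; a discordance flag records when the two disagree at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import CountMatrix
from .diffexpr import rank_test
from .normalize import to_percent_umi

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "DualTestResult",
    "compute_rq",
    "validate_housekeeping",
    "dual_test",
]

DEFAULT_HOUSEKEEPING = ["Actg1", "Actb", "Mrfap1", "Sdha"]


def compute_rq(
    bulk: pd.DataFrame, housekeeping: list[str] = DEFAULT_HOUSEKEEPING
) -> pd.DataFrame:
    """Counts divided by the replicate's housekeeping geometric mean.

    ``bulk`` is genes x replicates.  Every housekeeping gene must have
    a positive count in every replicate (a zero would make the
    geometric mean zero and is reported by gene and replicate).
    Scaling every count in a replicate by a constant leaves the RQ
    table unchanged.
    """
    missing = [g for g in housekeeping if g not in bulk.index]
    if missing:
        raise KeyError(f"housekeeping genes absent from counts: {missing}")
    hk = bulk.loc[housekeeping]
    zero = hk.le(0)
    if zero.to_numpy().any():
        g = zero.index[zero.any(axis=1)].tolist()
        r = zero.columns[zero.any(axis=0)].tolist()
        raise ValueError(
            f"zero housekeeping count: gene(s) {g} in replicate(s) {r}"
        )
    geomean = np.exp(np.log(hk.astype(float)).mean(axis=0))
    return bulk.astype(float).div(geomean, axis=1)


def validate_housekeeping(
    sc: CountMatrix,
    candidates,
    groups: dict[str, list[str]],
    stability_ceiling: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen housekeeping candidates on single-cell data.

    Per candidate: the coefficient of variation of per-cell %UMI
    pooled over all groups (stability), and a genotype-effect p-value
    (rank test for two groups, Kruskal-Wallis for more).  A candidate
    passes when it is both stable (CV <= ceiling) and genotype-neutral
    (p > alpha).  Absent candidates are reported as failing with a
    reason rather than raising.
    """
    pct = to_percent_umi(sc)
    rows = []
    for g in candidates:
        if g not in sc.gene_names:
            rows.append((g, np.nan, np.nan, False, "absent from matrix"))
            continue
        vals_by_group = [
            pct.gene_values(g, units) for units in groups.values()
        ]
        pooled = np.concatenate(vals_by_group)
        mean = pooled.mean()
        cv = float(pooled.std(ddof=1) / mean) if mean > 0 else np.inf
        if len(vals_by_group) == 2:
            p = rank_test(vals_by_group[0], vals_by_group[1])
        else:
            p = float(st.kruskal(*vals_by_group).pvalue)
        passes = cv <= stability_ceiling and p > alpha
        reason = "" if passes else (
            "unstable" if cv > stability_ceiling else "genotype effect"
        )
        rows.append((g, cv, p, passes, reason))
    return pd.DataFrame(
        rows,
        columns=["gene", "stability_score", "genotype_effect_p", "passes", "reason"],
    )


@dataclass(frozen=True)
class DualTestResult:
    p_t: float
    p_u: float
    mean_a: float
    mean_b: float
    pct_change: float
    significant: bool
    discordant: bool
    flag: str = ""


def dual_test(
    rq_a, rq_b, min_pct_change: float = 20.0, alpha: float = 0.05
) -> DualTestResult:
    """Welch t-test and Mann-Whitney U on two RQ value groups.

    The significance call mirrors the single-cell rule: more than
    ``min_pct_change`` percent change in the mean AND two-sided Welch
    p < ``alpha``.  The U-test is run alongside (exact where sample
    sizes permit); ``discordant`` flags the cases where the two tests
    disagree at ``alpha``.  Identical zero-variance groups get
    p = 1 by convention and a flag.
    """
    a = np.asarray(rq_a, dtype=float)
    b = np.asarray(rq_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group for the t-test")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    flag = ""
    if a.std() == 0 and b.std() == 0 and mean_a == mean_b:
        p_t = 1.0
        flag = "zero_variance"
    else:
        p_t = float(st.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p_t):
            p_t, flag = 1.0, "zero_variance"
    p_u = rank_test(a, b)
    if mean_a != 0:
        pct_change = abs(mean_b / mean_a - 1.0) * 100.0
    else:
        pct_change = np.inf if mean_b != 0 else 0.0
    significant = pct_change > min_pct_change and p_t < alpha
    discordant = (p_t < alpha) != (p_u < alpha)
    return DualTestResult(
        p_t=p_t,
        p_u=p_u,
        mean_a=mean_a,
        mean_b=mean_b,
        pct_change=float(pct_change),
        significant=significant,
        discordant=discordant,
        flag=flag,
    )
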