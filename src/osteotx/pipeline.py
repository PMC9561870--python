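"""End-to-end orchestration of the three analyses.

``run_single_cell`` chains QC -> %UMI normalization -> marker gating
-> Col1a1 binning -> per-bin differential expression -> running-average
trajectories, writing every intermediate to a run directory with a
content-hash manifest.  ``run_spatial`` gates osteoblast-enriched
spots and compares genotypes; ``run_bulk`` produces RQ tables and
dual-test calls.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .bulk_rq import compute_rq, dual_test
from .config import PipelineConfig
from .containers import CountMatrix
from .diffexpr import differential_expression
from .gating import bin_subpopulations, gate
from .io_qc import filter_cells, merge
from .normalize import to_percent_umi
from .trajectory import compare_profiles

log = logging.getLogger("osteotx")

__all__ = ["run_single_cell", "run_spatial", "run_bulk"]

DEFAULT_TRAJECTORY_GENES = ["Hspa5", "Hspa9", "Atf4", "Atf5"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, cfg: PipelineConfig) -> None:
    artifacts = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in artifacts
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _qc_and_merge(datasets: list[CountMatrix], cfg: PipelineConfig, out: Path):
    filtered = []
    reports = []
    for i, d in enumerate(datasets):
        f, rep = filter_cells(d, cfg.qc)
        log.info(
            "QC dataset %d: %d in, %d kept (%d low-feature, %d high-mito)",
            i, rep.n_in, rep.n_kept, rep.n_low_features, rep.n_high_mito,
        )
        filtered.append(f)
        reports.append(rep.to_frame().assign(dataset=i))
    pd.concat(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    return merge(filtered)


def run_single_cell(
    config: PipelineConfig,
    datasets: list[CountMatrix],
    out_dir,
    genes=None,
    trajectory_genes=None,
    contrast_column: str = "genotype",
    reference_level: str = "WT",
) -> dict:
    """QC, gate, bin, and contrast every non-reference genotype vs WT.

    Differential expression runs within the mature bin (the cells
    synthesizing the most procollagen, hence carrying the stress
    response); trajectories compare each genotype's running average
    against the reference along the Col1a1 gradient.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged = _qc_and_merge(datasets, config, out)
    if merged.n_units == 0:
        raise RuntimeError("stage QC: no units survived filtering")

    pct = to_percent_umi(merged)
    selected, report = gate(pct, config.gating)
    log.info("gating: %d of %d units selected", report.n_selected, report.n_in)
    pd.Series(selected).to_csv(
        out / "selected_units.txt", index=False, header=False
    )
    if not selected:
        raise RuntimeError("stage gating: no units selected")

    labels = bin_subpopulations(pct, selected, config.bins)
    labels.to_frame().to_csv(out / "bin_labels.tsv", sep="\t")

    meta = merged.unit_meta.loc[selected]
    levels = [
        g for g in meta[contrast_column].unique() if g != reference_level
    ]
    mature = config.bins.labels[-1]
    mature_units = labels[labels == mature].index
    if trajectory_genes is None:
        trajectory_genes = [
            g for g in DEFAULT_TRAJECTORY_GENES if g in merged.gene_names
        ]

    de_tables: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, dict] = {}
    for level in levels:
        ref_units = [
            u for u in mature_units
            if meta.loc[u, contrast_column] == reference_level
        ]
        alt_units = [
            u for u in mature_units if meta.loc[u, contrast_column] == level
        ]
        name = f"{level}_vs_{reference_level}_{mature}"
        table = differential_expression(
            merged, ref_units, alt_units, genes=genes, rule=config.de_rule,
            label_a=reference_level, label_b=level,
        )
        table.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        de_tables[name] = table
        log.info(
            "DE %s: %d/%d significant", name,
            int(table["significant"].sum()), len(table),
        )

        ref_all = [
            u for u in selected if meta.loc[u, contrast_column] == reference_level
        ]
        alt_all = [u for u in selected if meta.loc[u, contrast_column] == level]
        comparisons[level] = {}
        for gene in trajectory_genes:
            cmp_ = compare_profiles(
                merged, ref_all, alt_all, gene,
                covariate=config.bins.gene,
                window_size=config.trajectory_window,
                alpha_mark=config.trajectory_alpha,
                stride=config.trajectory_stride,
            )
            cmp_.table.to_csv(
                out / f"trajectory_{gene}_{level}.tsv", sep="\t", index=False
            )
            comparisons[level][gene] = cmp_
    _write_manifest(out, config)
    return {
        "merged": merged,
        "selected": selected,
        "bins": labels,
        "de": de_tables,
        "trajectories": comparisons,
    }


def run_spatial(
    config: PipelineConfig,
    spots: CountMatrix,
    out_dir,
    genes=None,
    contrast_column: str = "genotype",
    reference_level: str = "WT",
) -> dict:
    """Gate osteoblast-enriched spots, then genotype contrasts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not {"x", "y"} <= set(spots.unit_meta.columns):
        raise ValueError("spot metadata must carry x/y coordinates")
    pct = to_percent_umi(spots)
    selected, report = gate(pct, config.spot_gating)
    log.info(
        "spot gating: %d of %d spots selected", report.n_selected, report.n_in
    )
    pd.Series(selected).to_csv(
        out / "selected_spots.txt", index=False, header=False
    )
    result = {"selected": selected, "report": report, "de": None}
    if not selected:
        log.warning("no spots passed gating; skipping differential expression")
        _write_manifest(out, config)
        return result
    meta = spots.unit_meta.loc[selected]
    ref = [u for u in selected if meta.loc[u, contrast_column] == reference_level]
    alt = [u for u in selected if meta.loc[u, contrast_column] != reference_level]
    if len(ref) < 3 or len(alt) < 3:
        log.warning(
            "too few gated spots per group (%d vs %d); DE skipped",
            len(ref), len(alt),
        )
        _write_manifest(out, config)
        return result
    table = differential_expression(
        spots, ref, alt, genes=genes, rule=config.de_rule,
        label_a=reference_level, label_b="mut",
    )
    table.to_csv(out / "de_spots.tsv", sep="\t", index=False)
    result["de"] = table
    _write_manifest(out, config)
    return result


def run_bulk(
    config: PipelineConfig,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    out_dir,
    genes=None,
    contrast_column: str = "genotype",
    reference_level: str = "WT",
) -> dict:
    """RQ-normalize bulk counts and run the dual significance tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.exclude_days and "day" in meta.columns:
        keep = ~meta["day"].isin(config.exclude_days)
        meta = meta.loc[keep]
        counts = counts[meta.index]
        log.info("bulk: %d replicates after day exclusion", len(meta))
    rq = compute_rq(counts, config.housekeeping)
    rq.to_csv(out / "rq.tsv", sep="\t")
    ref_cols = meta.index[meta[contrast_column] == reference_level]
    alt_cols = meta.index[meta[contrast_column] != reference_level]
    if genes is None:
        genes = [g for g in rq.index if g not in config.housekeeping]
    rows = []
    for g in genes:
        res = dual_test(
            rq.loc[g, ref_cols], rq.loc[g, alt_cols],
            min_pct_change=config.de_rule.min_pct_change,
            alpha=config.de_rule.alpha,
        )
        rows.append(
            (g, res.mean_a, res.mean_b, res.pct_change, res.p_t, res.p_u,
             res.significant, res.discordant, res.flag)
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "mean_ref", "mean_alt", "pct_change", "p_t", "p_u",
                 "significant", "discordant", "flag"],
    )
    table.to_csv(out / "bulk_tests.tsv", sep="\t", index=False)
    _write_manifest(out, config)
    return {"rq": rq, "tests": table}
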