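"""Pipeline configuration: one YAML-serializable object per run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bulk_rq import DEFAULT_HOUSEKEEPING
from .diffexpr import SignificanceRule
from .gating import GatingConfig, SubpopulationBins
from .io_qc import QCConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]

_DEFAULT_CELL_GATE = GatingConfig(
    inclusion=[("Col1a1", 20.0), ("Runx2", 1.0), ("Sp7", 1.0), ("Ibsp", 1.0)],
    exclusion=[],
    mode="cell",
    scale="count",
)
_DEFAULT_SPOT_GATE = GatingConfig(
    inclusion=[
        ("Col1a1", 1.0),
        ("Runx2", 0.005),
        ("Sp7", 0.01),
        ("Ibsp", 0.02),
    ],
    exclusion=[("Col2a1", 0.15), ("Col10a1", 0.03)],
    mode="spot",
    scale="percent",
)


@dataclass
class PipelineConfig:
    """Everything a run needs, round-trippable through YAML."""

    qc: QCConfig = field(default_factory=QCConfig)
    gating: GatingConfig = field(default_factory=lambda: _DEFAULT_CELL_GATE)
    spot_gating: GatingConfig = field(default_factory=lambda: _DEFAULT_SPOT_GATE)
    bins: SubpopulationBins = field(default_factory=SubpopulationBins)
    de_rule: SignificanceRule = field(default_factory=SignificanceRule)
    trajectory_window: int = 20
    trajectory_alpha: float = 0.01
    trajectory_stride: int = 1
    housekeeping: list[str] = field(
        default_factory=lambda: list(DEFAULT_HOUSEKEEPING)
    )
    exclude_days: list[int] = field(default_factory=lambda: [8])
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "qc": {
                "min_features": self.qc.min_features,
                "max_features": self.qc.max_features,
                "max_mito_fraction": self.qc.max_mito_fraction,
                "death_markers": list(self.qc.death_markers),
                "death_screen_alpha": self.qc.death_screen_alpha,
            },
            "gating": self.gating.to_dict(),
            "spot_gating": self.spot_gating.to_dict(),
            "bins": {
                "gene": self.bins.gene,
                "edges": list(self.bins.edges),
                "labels": list(self.bins.labels),
            },
            "de_rule": {
                "min_pct_change": self.de_rule.min_pct_change,
                "alpha": self.de_rule.alpha,
                "pseudocount": self.de_rule.pseudocount,
            },
            "trajectory": {
                "window_size": self.trajectory_window,
                "alpha_mark": self.trajectory_alpha,
                "stride": self.trajectory_stride,
            },
            "bulk": {
                "housekeeping": list(self.housekeeping),
                "exclude_days": list(self.exclude_days),
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "qc" in d:
            cfg.qc = QCConfig(**d["qc"])
        if "gating" in d:
            cfg.gating = GatingConfig.from_dict(d["gating"])
        if "spot_gating" in d:
            cfg.spot_gating = GatingConfig.from_dict(d["spot_gating"])
        if "bins" in d:
            b = d["bins"]
            cfg.bins = SubpopulationBins(
                gene=b.get("gene", "Col1a1"),
                edges=tuple(b.get("edges", (0.75, 3.5))),
                labels=tuple(b.get("labels", ("eOB", "dOB", "mOB"))),
            )
        if "de_rule" in d:
            cfg.de_rule = SignificanceRule(**d["de_rule"])
        if "trajectory" in d:
            t = d["trajectory"]
            cfg.trajectory_window = int(t.get("window_size", 20))
            cfg.trajectory_alpha = float(t.get("alpha_mark", 0.01))
            cfg.trajectory_stride = int(t.get("stride", 1))
        if "bulk" in d:
            cfg.housekeeping = list(
                d["bulk"].get("housekeeping", DEFAULT_HOUSEKEEPING)
            )
            cfg.exclude_days = list(d["bulk"].get("exclude_days", [8]))
        cfg.seed = int(d.get("seed", 0))
        return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
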