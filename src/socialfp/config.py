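"""Run configuration: analysis parameters, cohort design, paths.

Defaults follow the task protocol: 5-min sessions, 0.5 s merge gap,
(6, 19) s bout-category edges, 1-min bins, peri-event window -2 to +5 s at
0.1 s bins with the 2 s pre-onset baseline, AUC over [0, 5] s.  Configs
load from / save to simple YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SimConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    input_dir: str = "cohort"
    output_dir: str = "results"
    tasks: tuple[str, ...] = ("social_vs_empty",)
    conditions: tuple[str, ...] = ("satiety+none",)
    seed: int = 0
    n_per_genotype: dict = field(default_factory=lambda: {"WT": 10, "HET": 12, "KO": 9})
    # behavior
    merge_gap_s: float = 0.5
    bin_s: float = 60.0
    category_edges: tuple[float, float] = (6.0, 19.0)
    # photometry
    peri_window: tuple[float, float] = (-2.0, 5.0)
    peri_bin_s: float = 0.1
    baseline_s: float = 2.0
    auc_interval: tuple[float, float] = (0.0, 5.0)
    exclude_overlapping_baselines: bool = False
    exclude_cross_stimulus_overlap: bool = True
    qc_drift_thresh: float = 0.01
    qc_snr_thresh: float = 3.0
    apply_qc_exclusion: bool = False
    # statistics
    n_perm: int = 10_000
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        self.tasks = tuple(self.tasks)
        self.conditions = tuple(self.conditions)
        self.category_edges = tuple(self.category_edges)
        self.peri_window = tuple(self.peri_window)
        self.auc_interval = tuple(self.auc_interval)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.validate()

    def validate(self) -> None:
        for name in ("merge_gap_s", "bin_s", "peri_bin_s", "baseline_s",
                     "qc_drift_thresh", "qc_snr_thresh", "n_perm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.peri_window
        if not lo < 0 < hi:
            raise ValueError("peri-event window must straddle the onset")
        if self.baseline_s > -lo + 1e-9:
            raise ValueError("baseline must fit inside the pre-onset window")
        alo, ahi = self.auc_interval
        if alo < lo - 1e-9 or ahi > hi + 1e-9:
            raise ValueError("AUC interval must lie within the peri-event window")
        if not self.category_edges[0] < self.category_edges[1]:
            raise ValueError("category edges must be strictly increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("tasks", "conditions", "category_edges", "peri_window", "auc_interval"):
            d[k] = list(d[k])
        return d


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
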