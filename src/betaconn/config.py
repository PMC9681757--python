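"""Structured configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis sequence, with the study's defaults.

    Community parameters follow the study protocol (Louvain gamma = 1 run
    1000 times, consensus tau = 0.5 with 1000 runs per cycle); reduce
    ``louvain_runs`` for quick exploratory passes.  All randomness
    derives from ``seed`` via stage-salted streams.
    """

    # input paths (None -> simulate a synthetic cohort)
    data_dir: str | None = None
    out_dir: str = "results/run"
    cohort: str = "default"  # "default" | "connector" (synthetic cohorts)
    # restrict the analysis to a subset of conditions (None -> all)
    conditions: list[str] | None = None

    # densities (%)
    densities: list[float] = field(default_factory=lambda: [15.0, 22.0])
    density_step: float = 1.0
    primary_density: float = 15.0
    select_range: bool = False
    full_fraction: float = 0.90
    edge_ranking: str = "signed"

    # community detection
    gamma: float = 1.0
    louvain_runs: int = 1000
    tau: float = 0.5
    consensus_max_cycles: int = 50

    # hub analysis
    target_node: int = 262
    hub_fraction: float = 0.05

    # statistics
    n_perm: int = 10000
    alpha: float = 0.05

    write_matrices: bool = False
    seed: int = 0
    # programmatic overrides for the synthetic ground truth (e.g. a small
    # cohort for quick runs); not meant for YAML configs
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.primary_density < 100:
            raise ValueError("primary density must be in (0, 100)")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub fraction must be in (0, 1)")
        if self.louvain_runs < 1 or self.n_perm < 1:
            raise ValueError("run counts must be positive")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
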