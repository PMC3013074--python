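"""Pipeline configuration: thresholds, seed, and stage toggles."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """End-to-end run parameters.

    Thresholds carry the analysis defaults: DE calls at P<0.01 and
    FDR<=0.001, detectability at 1 TPM, recurrence over >=2 samples, hairpin
    stability below −20 kcal/mol, small-RNA inserts >=18 nt, tag mapping
    with at most one mismatch.
    """

    seed: int = 0
    p_max: float = 0.01
    fdr_max: float = 0.001
    detect_tpm: float = 1.0
    min_samples: int = 2
    energy_threshold: float = -20.0
    min_len: int = 18
    mismatches: int = 1
    pseudo_tpm: float = 0.5
    cluster_gap: int = 10_000
    min_cluster_size: int = 3
    gsea_weight: float = 1.0
    gsea_permutations: int = 200
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(
        default_factory=lambda: {
            "tags": True,
            "smallrna": True,
            "diffexp": True,
            "pathways": True,
        }
    )

    def validate(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must lie in (0, 1]")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.detect_tpm < 0:
            raise ValueError("detect_tpm must be non-negative")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold must be negative (kcal/mol)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.mismatches not in (0, 1):
            raise ValueError("mismatches must be 0 or 1")
        self.simulation.seed = self.seed
        self.simulation.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        cfg.simulation = SimulationConfig(**{**asdict(cfg.simulation), **sim})
        return cfg
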