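"""Pipeline configuration: one object holding every stage's parameters.

Defaults encode the study-standard settings: 95% outlier ellipse, Blom
offset 3/8, k = 100 resamplings retaining 85% per group, 1000
permutations, PCLRC at 1000 iterations / 0.75 subsample fraction / 0.30
retention quantile, edge thresholds p >= 0.95 and |r| >= 0.6, FDR 0.05
and pathway impact > 0.01.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # input
    input_path: str | None = None
    input_format: str = "wide_csv"
    design_path: str | None = None  # synthetic design YAML (alternative to input)
    group_aliases: dict[str, str] = field(default_factory=dict)
    pairs: list[list[str]] = field(default_factory=list)  # [] = all pairs

    # preprocessing
    outlier_confidence: float = 0.95
    blom_offset: float = 0.375
    univariate_input: str = "sqrt_raw"  # sqrt_raw | int | sqrt_int

    # classification
    rf_k: int = 100
    rf_train_fraction: float = 0.85
    rf_trees: int = 500
    rf_n_perm: int = 1000
    rf_perm_k: int = 2
    rf_perm_trees: int = 100

    # pclrc / networks
    pclrc_iterations: int = 1000
    pclrc_subsample_fraction: float = 0.75
    pclrc_retention_quantile: float = 0.30
    p_min: float = 0.95
    r_min: float = 0.6

    # differential connectivity
    diffcon_n_perm: int = 1000
    diffcon_perm_iterations: int = 100
    diffcon_statistic: str = "weighted_strength"

    # thresholds
    fdr_alpha: float = 0.05
    impact_min: float = 0.01

    # enrichment
    pathway_library: str | None = None  # None -> shipped toy library

    # orchestration
    seed: int = 0
    output_dir: str = "metabonet_out"

    def __post_init__(self) -> None:
        if not (0.0 < self.outlier_confidence <= 1.0):
            raise ValueError("outlier_confidence must be in (0, 1]")
        if self.univariate_input not in ("sqrt_raw", "int", "sqrt_int"):
            raise ValueError("univariate_input must be sqrt_raw, int or sqrt_int")
        for name, lo, hi in (
            ("p_min", 0.0, 1.01),
            ("r_min", 0.0, 1.0),
            ("fdr_alpha", 0.0, 1.0),
            ("pclrc_subsample_fraction", 0.0, 1.0),
            ("pclrc_retention_quantile", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.seed is None:
            raise ValueError("a master seed is mandatory (stochastic stages)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
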