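"""Run configuration: the analysis thresholds and generator parameters.

Defaults are the published constants of the analysis this package
reimplements: MA significance 5e-3, motif presence FDR 1e-3, DE alpha 0.05,
promoter half-width 2 kb, enhancer limit 20 kb.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import ExprSimConfig, GenomeSimConfig, PeakSimConfig


@dataclass(frozen=True)
class AnalysisConfig:
    binding_threshold: float = 5e-3      # MA-stat p cut for enriched peaks
    presence_fdr: float = 1e-3           # BH FDR for motif presence calls
    de_alpha: float = 0.05               # adjusted-p cut for DE classes
    promoter_bp: int = 2000
    enhancer_bp: int = 20000
    ma_pseudocount: float = 1.0
    pwm_pseudocount: float = 0.1
    scan_both_strands: bool = True
    background: str = "sequences"        # "sequences" (order-0 estimate) or "uniform"
    pvalue_granularity: float = 1e-3     # DP score discretization, log2 units
    n_decoys: int = 20
    seed: int = 0
    peaks: PeakSimConfig = field(default_factory=PeakSimConfig)
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    expression: ExprSimConfig = field(default_factory=ExprSimConfig)

    def __post_init__(self) -> None:
        for name in ("binding_threshold", "presence_fdr", "de_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.promoter_bp <= 0 or self.enhancer_bp <= self.promoter_bp:
            raise ValueError("need 0 < promoter_bp < enhancer_bp")
        if self.background not in ("sequences", "uniform"):
            raise ValueError("background must be 'sequences' or 'uniform'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Flat key-value YAML; nested generator settings live under
        ``peaks:``, ``genome:`` and ``expression:``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for name, sub in (("peaks", PeakSimConfig), ("genome", GenomeSimConfig),
                          ("expression", ExprSimConfig)):
            if name in kwargs:
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)
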