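"""Pipeline configuration: the analysis thresholds in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


def _default_pairs() -> list[tuple[str, str]]:
    # CMS1 left out of resampling by default: too few MSS samples
    return [("CMS2", "CMS3"), ("CMS2", "CMS4"), ("CMS3", "CMS4")]


@dataclass
class PipelineConfig:
    """Thresholds and sizes for every pipeline stage.

    The defaults are the analysis constants used throughout: +/-0.15
    relative-log thresholds for gain/loss calls, >=5 additional copies for
    amplification and >=15 for high-level, <=50 genes for focality, 0.1
    variance floor, FDR 0.05, fold change 1.2, 2.2n ploidy dichotomy,
    group-size floors of 10 (genome-wide) and 3 (resampling), and a 5-year
    survival horizon.
    """

    gain_threshold: float = 0.15
    loss_threshold: float = -0.15
    amp_min_additional: int = 5
    high_level_threshold: int = 15
    focal_max_genes: int = 50
    min_tumors_recurrent: int = 2
    min_variance: float = 0.1
    fdr_alpha: float = 0.05
    fold_change: float = 1.2
    ploidy_cutoff: float = 2.2
    min_per_group_genome: int = 10
    min_per_group_resample: int = 3
    resample_iterations: int = 1000
    resample_per_group: int = 20
    resample_variant: str = "ii"
    resample_pairs: list[tuple[str, str]] = field(default_factory=_default_pairs)
    gene_subsample: int = 250
    survival_horizon: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resample_pairs"] = [list(p) for p in self.resample_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "resample_pairs" in d:
            d["resample_pairs"] = [tuple(p) for p in d["resample_pairs"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def __post_init__(self) -> None:
        if self.gain_threshold <= 0 or self.loss_threshold >= 0:
            raise ValueError("gain threshold must be positive, loss negative")
        for name in ("amp_min_additional", "high_level_threshold", "focal_max_genes",
                     "min_per_group_genome", "min_per_group_resample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
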