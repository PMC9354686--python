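"""Pipeline configuration: one structured YAML file covering every stage.

Every threshold the analysis depends on appears here with the study value
as its default: the 0.5 zero-count fraction and mean-10 feature filters,
the gene (|log2FC| > 1.0, BH p < 1e-5) and miR (|log2FC| > 0.5, raw
p < 1e-5) DE thresholds, and K = 100,000 for top-K retention (the
synthetic default study overrides K to the same retention *fraction* at
its smaller scale).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    max_zero_fraction: float = 0.5
    min_mean: float = 10.0
    annotation_filter_genes: bool = True
    annotation_filter_mirs: bool = False


@dataclass
class DEConfig:
    gene_lfc: float = 1.0
    gene_p: float = 1e-5
    gene_use_adjusted: bool = True
    mir_lfc: float = 0.5
    mir_p: float = 1e-5
    mir_use_adjusted: bool = False
    dispersion_mode: str = "moments"
    pseudocount: float = 0.5


@dataclass
class NetworkConfig:
    k: int = 100_000
    n_bins: int | str = "auto"
    bias_correction: bool = False
    rank_transform: bool = True


@dataclass
class CompareConfig:
    level: str = "topk"


@dataclass
class PipelineConfig:
    seed: int = 0
    use_default_study: bool = True  # simulate with the built-in default study
    k_override: int | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    de: DEConfig = field(default_factory=DEConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sub = {
            "preprocess": PreprocessConfig,
            "de": DEConfig,
            "network": NetworkConfig,
            "compare": CompareConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                known = sub[key].__dataclass_fields__
                bad = set(value) - set(known)
                if bad:
                    raise ValueError(f"unknown config keys in '{key}': {sorted(bad)}")
                kwargs[key] = sub[key](**value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
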