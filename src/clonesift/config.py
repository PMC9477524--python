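"""Pipeline configuration: one validated object covering every stage.

Defaults follow the study conditions used throughout this package:
theta = 0.05, h = 0.5, epsilon = 0.01, posterior threshold K = 0.05,
6 Laplacian eigenvectors, inertia-gap factor 0.75, minimum cluster size
500 cells and minimum pooled coverage 9.  Serialized as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .clustering import ClusterParams
from .locus_filter import FilterParams
from .similarity import SimilarityParams
from .variant_caller import CallerParams


@dataclass
class PipelineConfig:
    filter: FilterParams = field(default_factory=FilterParams)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int = 0
    threads: int = 1
    min_base_qual: int = 30
    min_map_qual: int = 30

    def __post_init__(self) -> None:
        self.cluster.seed = self.seed

    def to_dict(self) -> dict[str, Any]:
        return {
            "filter": dataclasses.asdict(self.filter),
            "similarity": dataclasses.asdict(self.similarity),
            "cluster": dataclasses.asdict(self.cluster),
            "caller": dataclasses.asdict(self.caller),
            "seed": self.seed,
            "threads": self.threads,
            "min_base_qual": self.min_base_qual,
            "min_map_qual": self.min_map_qual,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for name, klass in (
            ("filter", FilterParams),
            ("similarity", SimilarityParams),
            ("cluster", ClusterParams),
            ("caller", CallerParams),
        ):
            section = data.pop(name, {}) or {}
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - valid
            if unknown:
                raise ValueError(f"unknown {name} option(s): {sorted(unknown)}")
            kwargs[name] = klass(**section)
        for scalar in ("seed", "threads", "min_base_qual", "min_map_qual"):
            if scalar in data:
                kwargs[scalar] = data.pop(scalar)
        if data:
            raise ValueError(f"unknown config section(s): {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
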