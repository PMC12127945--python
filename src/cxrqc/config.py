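"""Pipeline configuration: one dataclass tree with every stage default,
loadable from YAML and snapshotted into each report."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .annotation import AnnotationConfig
from .geometry import (DEFAULT_ASPECT_LOWER, DEFAULT_ASPECT_UPPER,
                       DEFAULT_COLLIM_THRESHOLD, DEFAULT_PAD_TOL,
                       AspectRatioBounds)
from .quality import QualityThresholds


@dataclass
class GeometryConfig:
    aspect_lower: float = DEFAULT_ASPECT_LOWER
    aspect_upper: float = DEFAULT_ASPECT_UPPER
    pad_tol: float = DEFAULT_PAD_TOL
    collim_threshold: float = DEFAULT_COLLIM_THRESHOLD
    rotation_enabled: bool = True

    def aspect_bounds(self) -> AspectRatioBounds:
        return AspectRatioBounds(self.aspect_lower, self.aspect_upper)


@dataclass
class ProjectionConfig:
    threshold: float = 0.5
    model_path: Optional[str] = None


@dataclass
class EvaluationConfig:
    n_boot: int = 1000


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, sub):
            fields = klass.__dataclass_fields__
            bad = set(sub) - set(fields)
            if bad:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            coerced = {}
            for k, v in sub.items():
                if isinstance(v, list):
                    v = tuple(v)
                coerced[k] = v
            return klass(**coerced)

        return cls(
            geometry=build(GeometryConfig, d.get("geometry", {})),
            annotation=build(AnnotationConfig, d.get("annotation", {})),
            projection=build(ProjectionConfig, d.get("projection", {})),
            quality=build(QualityThresholds, d.get("quality", {})),
            evaluation=build(EvaluationConfig, d.get("evaluation", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
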