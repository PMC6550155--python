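"""Run configuration: one schema-checked object bundling every knob.

Every under-specified pipeline parameter (segmentation thresholds, packet
sizes, smoothing windows, forest size, simulator profiles...) is visible in
one YAML-serializable structure, round-trips through a config file, and can
be dumped with its defaults so runs are versionable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .classifier import CVConfig
from .dynamics_features import DynamicsConfig
from .spectral import SpectralConfig
from .static_features import StaticConfig
from .synthetic import CohortSpec, WriterProfile, default_profiles


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Nested configuration for a full pipeline run."""

    static: StaticConfig = dataclasses.field(default_factory=StaticConfig)
    dynamics: DynamicsConfig = dataclasses.field(default_factory=DynamicsConfig)
    cv: CVConfig = dataclasses.field(default_factory=CVConfig)
    simulator: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        profiles = default_profiles()
        sim = dataclasses.asdict(self.simulator)
        sim["td_profile"] = dataclasses.asdict(self.simulator.td_profile or profiles["td"])
        sim["d_profile"] = dataclasses.asdict(self.simulator.d_profile or profiles["d"])
        cv = dataclasses.asdict(self.cv)
        cv["feature_subset"] = list(self.cv.feature_subset) if self.cv.feature_subset else None
        return {
            "static": dataclasses.asdict(self.static),
            "dynamics": dataclasses.asdict(self.dynamics),
            "cv": cv,
            "simulator": sim,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        static = StaticConfig(**d.get("static", {}))
        dyn = dict(d.get("dynamics", {}))
        if isinstance(dyn.get("spectral"), dict):
            dyn["spectral"] = SpectralConfig(**dyn["spectral"])
        dynamics = DynamicsConfig(**dyn)
        cv = dict(d.get("cv", {}))
        if cv.get("feature_subset") is not None:
            cv["feature_subset"] = tuple(cv["feature_subset"])
        sim = dict(d.get("simulator", {}))
        for key in ("td_profile", "d_profile"):
            if isinstance(sim.get(key), dict):
                sim[key] = WriterProfile(**sim[key])
        return cls(static=static, dynamics=dynamics, cv=CVConfig(**cv),
                   simulator=CohortSpec(**sim), seed=int(d.get("seed", 0)),
                   log_level=str(d.get("log_level", "INFO")))

    def dump(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(self.dump().encode()).hexdigest()[:12]
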