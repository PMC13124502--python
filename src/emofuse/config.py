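"""Declarative run configuration with provenance hashing.

``RunConfig`` bundles every tunable constant of the pipeline — the
synthetic-experiment design, preprocessing constants, feature windowing,
screening alpha, classifier training settings and cross-validation
layout — and can round-trip through a flat JSON file. ``config_hash``
gives a stable digest for provenance blocks, so a run can be reproduced
bit-identically from (config, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .features import Windowing
from .lstm import TrainConfig
from .synth import EmotionProfile, SynthConfig

__all__ = ["RunConfig", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    # preprocessing constants
    notch_hz: float = 50.0
    rejection_uv: float = 100.0
    ectopic_tolerance: float = 0.20
    gsr_lowpass_hz: float = 0.3
    scr_threshold_us: float = 0.01
    # feature constants
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    window: Windowing = field(default_factory=Windowing)
    # screening / modeling
    alpha: float = 0.05
    train: TrainConfig = field(default_factory=TrainConfig)
    n_folds: int = 5
    val_fraction: float = 0.15

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=seed),
            train=replace(self.train, seed=seed),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["profiles"] = {
            lab: asdict(p) for lab, p in self.synth.profiles.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = dict(d.pop("synth", {}))
        if "profiles" in synth:
            synth["profiles"] = {
                lab: EmotionProfile(**{**p, "alpha_asym_shift": tuple(p["alpha_asym_shift"])})
                for lab, p in synth["profiles"].items()
            }
        train = TrainConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.pop("train", {}).items()
        })
        window = Windowing(**d.pop("window", {}))
        return cls(synth=SynthConfig(**synth), train=train, window=window, **d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def config_hash(config: RunConfig) -> str:
    """Stable short digest of the full configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
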