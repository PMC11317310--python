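"""Pipeline configuration and deterministic seed derivation.

All randomness in a run descends from one master seed. Purpose-specific
seeds are derived as
``SeedSequence((master, crc32(tag), *indices)).generate_state(1) % 2**31``,
so every stage (fold plans, per-fold penalty CV, bootstrap, permutation)
is independently and reproducibly seeded, which is what makes the
from-scratch permutation refits exactly repeatable.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError

__all__ = [
    "PropensityConfig", "BenefitConfig", "CVConfig", "InferenceConfig",
    "PipelineConfig", "child_seed",
]


def child_seed(master: int, tag: str, *indices: int) -> int:
    h = zlib.crc32(tag.encode())
    ss = np.random.SeedSequence((int(master), h, *map(int, indices)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PropensityConfig:
    cv_folds: int = 10
    lambda_rule: str = "min"
    truncation: float = 0.01
    n_lambda: int = 60
    lambda_min_ratio: float | None = None


@dataclass
class BenefitConfig:
    cv_folds: int = 10
    lambda_rule: str = "min"
    outcome: str = "neuro"
    n_lambda: int = 60
    lambda_min_ratio: float | None = None


@dataclass
class CVConfig:
    outer_k: int = 5
    inner_k: int = 10


@dataclass
class InferenceConfig:
    bootstrap_B: int = 10000
    perm_B: int = 999
    bootstrap_refit_full: bool = False
    max_redraws: int = 10


@dataclass
class PipelineConfig:
    propensity: PropensityConfig = field(default_factory=PropensityConfig)
    benefit: BenefitConfig = field(default_factory=BenefitConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    infer: InferenceConfig = field(default_factory=InferenceConfig)
    outcomes: tuple = ("neuro", "survival")
    seed: int = 0

    def validate(self) -> None:
        if self.cv.outer_k < 2 or self.cv.inner_k < 2:
            raise ConfigurationError("outer_k and inner_k must be >= 2")
        for rule in (self.propensity.lambda_rule, self.benefit.lambda_rule):
            if rule not in ("min", "1se"):
                raise ConfigurationError(f"unknown lambda_rule {rule!r}")
        for o in self.outcomes:
            if o not in ("neuro", "survival"):
                raise ConfigurationError(f"unknown outcome {o!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        cfg = cls(
            propensity=PropensityConfig(**d.pop("propensity", {})),
            benefit=BenefitConfig(**d.pop("benefit", {})),
            cv=CVConfig(**d.pop("cv", {})),
            infer=InferenceConfig(**d.pop("infer", {})),
            outcomes=tuple(d.pop("outcomes", ("neuro", "survival"))),
            seed=int(d.pop("seed", 0)),
        )
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
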