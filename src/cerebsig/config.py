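"""Configuration objects for cohort simulation and the full pipeline.

``SimulationConfig`` fixes the statistical structure of a synthetic cohort:
how severe each subtype's degeneration is, how the cerebellum scales with
overall brain size, how noisy the voxel intensities are, and how the ataxia
score is coupled to degeneration in motor regions.  All randomness flows from
the single ``seed`` field, so a config identifies one cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Group label used for healthy controls throughout the package.
CONTROL_GROUP = "HC"

#: Default subtype labels for three polyglutamine-ataxia analogs.  The second
#: subtype emulates the clinically interesting scenario of a group that is
#: less degenerated overall but whose pattern weights motor regions more.
DEFAULT_SUBTYPES = ("SCA2like", "SCA3like", "SCA7like")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generative model.

    The generative model for a patient's modulated gray-matter map is

        map = f * (template - s * pattern) + noise,   clipped at 0,

    where ``s`` is the patient's degeneration severity (intensity units),
    ``pattern`` is the subtype's unit-mean spatial signature plus a smooth
    per-patient deviation field, ``f`` is a multiplicative brain-size factor
    coupled to cerebrum volume, and noise is a spatially smoothed Gaussian
    field.  Controls have ``s = 0``.  The ataxia score is
    ``sara = a + b * (mean true degeneration over motor regions) + eps``.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_regions: int = 12                       # total regions incl. 3 nucleus stand-ins
    n_motor_regions: int = 2                  # cortical regions flagged as motor

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {CONTROL_GROUP: 15, "SCA2like": 14,
                                 "SCA3like": 17, "SCA7like": 23})
    # Per-group severity distribution (intensity-loss units; template mean ~0.7,
    # so 0.12 is ~17% relative gray-matter reduction).  The SCA3 analog is
    # configured less degenerated overall: that subtype tends to present
    # clinically before much cerebellar atrophy has accumulated.
    severity_mean: dict[str, float] = field(
        default_factory=lambda: {"SCA2like": 0.12, "SCA3like": 0.07,
                                 "SCA7like": 0.12})
    severity_sd: dict[str, float] = field(
        default_factory=lambda: {"SCA2like": 0.04, "SCA3like": 0.03,
                                 "SCA7like": 0.04})

    # Cerebrum volume (mm^3) and its multiplicative coupling to cerebellar size.
    brain_size_mean: float = 1.1e6
    brain_size_sd: float = 0.8e5
    brain_coupling: float = 0.4

    # Additive Gaussian noise on intensities.  VBM maps are spatially
    # autocorrelated, so the noise field is smoothed with this kernel (voxels)
    # and rescaled to marginal sd = noise_sd; 0 gives white voxel noise.
    noise_sd: float = 0.02
    noise_smooth_sigma: float = 1.5

    # Per-patient individuality of the degeneration pattern: a smooth,
    # zero-mean random field with this sd (relative to the unit-mean
    # signature) is added to the group signature before severity scaling.
    # Real patients do not degenerate in lockstep with their subtype's mean
    # pattern; this variability scales with severity, unlike scanner noise.
    pattern_jitter_sd: float = 0.15
    pattern_jitter_smooth_sigma: float = 2.0

    # Control-template construction: flat baseline plus a smooth field.
    template_baseline: float = 0.7
    template_variation: float = 0.05

    # Signature shape: log-normal region weights, subtype-specific elevated
    # regions, and a per-subtype multiplier on motor-region weight.  The SCA3
    # analog weights motor regions more and the nuclei less, reproducing the
    # "same symptoms, less overall degeneration" scenario.
    signature_region_sd: float = 0.25
    signature_boost: float = 1.0              # added weight on a subtype's own regions
    motor_emphasis: dict[str, float] = field(
        default_factory=lambda: {"SCA2like": 0.8, "SCA3like": 3.5,
                                 "SCA7like": 0.8})
    nucleus_scale: dict[str, float] = field(
        default_factory=lambda: {"SCA2like": 1.0, "SCA3like": 0.5,
                                 "SCA7like": 1.0})
    signature_smooth_sigma: float = 1.0       # voxels; 0 disables smoothing

    # Ataxia-score coupling: sara = a + b * mean motor degeneration + N(0, sd).
    sara_intercept: float = 1.0
    sara_slope: float = 90.0
    sara_noise_sd: float = 4.5

    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)  # type: ignore[assignment]
        if len(self.grid_shape) != 3 or any(v <= 0 for v in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if self.n_regions < 4:
            raise ConfigurationError(
                "n_regions must be >= 4 (at least one cortical region plus "
                "three nucleus stand-ins)")
        if self.n_motor_regions < 1:
            raise ConfigurationError("need at least one motor region")
        if self.n_motor_regions > self.n_regions - 3:
            raise ConfigurationError("more motor regions than cortical regions")
        for name, val in (("brain_size_sd", self.brain_size_sd),
                          ("noise_sd", self.noise_sd),
                          ("sara_noise_sd", self.sara_noise_sd)):
            if val < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {val}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigurationError(f"group {g!r} size must be >= 2, got {n}")
        for g, sd in self.severity_sd.items():
            if sd < 0:
                raise ConfigurationError(f"severity_sd[{g!r}] must be >= 0")

    @property
    def subtypes(self) -> list[str]:
        return [g for g in self.group_sizes if g != CONTROL_GROUP]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
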