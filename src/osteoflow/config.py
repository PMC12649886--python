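"""Generator and run configuration.

The defaults encode the study design the pipeline targets: 6 scaffolds per
culture condition, 30 ROIs per scaffold, a 300 s observation window sampled
once every 1.73 s, a 2-fold wave threshold, and condition-dependent effect
structure (a disuse-enriched high-amplitude subpopulation, PMD-coupled
amplitude amplification under disuse, and wounding fractions elevated by
disuse).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its valid range."""


@dataclass
class SynthConfig:
    # design
    n_scaffolds_per_condition: int = 6
    n_rois_per_scaffold: int = 30
    window_s: float = 300.0
    dt_s: float = 1.73
    # baseline / nuisance structure
    baseline_level: float = 100.0          # a.u.
    drift_slope: float = 0.02              # a.u./s
    artifact_rate: float = 0.01            # events/s (motion bumps)
    artifact_amp_frac: float = 0.3         # fraction of baseline, sub-wave by design
    noise_sd_frac: float = 0.03            # multiplicative Gaussian noise
    # calcium wave structure
    wave_rate_control: float = 0.012       # events/s
    wave_rate_disuse: float = 0.008        # disuse shows fewer waves on average
    amp_lognorm_mu: float = 1.1            # log peak-fold location (median fold ~3)
    amp_lognorm_sigma: float = 0.35
    amp_min_fold: float = 1.05             # floor applied to drawn peak folds
    wave_duration_mean_s: float = 20.0
    wave_duration_sd_s: float = 6.0
    wave_onset_min_s: float = 25.0         # quiet pre-event plateau for baselining
    # high-amplitude subpopulation (F/Fo > 10)
    high_responder_frac_control: float = 0.04
    high_responder_frac_disuse: float = 0.10
    high_responder_amp_fc: float = 10.0
    # membrane disruption coupling
    pmd_frac_control: float = 0.05
    pmd_frac_disuse: float = 0.15
    pmd_amp_multiplier: float = 3.0        # applied to disuse x PMD+ wave folds only
    # sustained (never-returning) signals, a proxy for lost membrane integrity
    sustained_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds_per_condition < 1 or self.n_rois_per_scaffold < 1:
            raise ConfigError("scaffold and ROI counts must be >= 1")
        for name in ("window_s", "dt_s", "baseline_level", "wave_duration_mean_s",
                     "wave_duration_sd_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if round(self.window_s / self.dt_s) + 1 < 2:
            raise ConfigError("window_s / dt_s must yield at least 2 frames")
        for name in ("high_responder_frac_control", "high_responder_frac_disuse",
                     "pmd_frac_control", "pmd_frac_disuse", "sustained_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("artifact_rate", "wave_rate_control", "wave_rate_disuse",
                     "noise_sd_frac", "artifact_amp_frac", "drift_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.pmd_amp_multiplier < 1.0:
            raise ConfigError("pmd_amp_multiplier must be >= 1")
        if self.amp_min_fold < 1.0:
            raise ConfigError("amp_min_fold must be >= 1")
        if self.high_responder_amp_fc < 1.0:
            raise ConfigError("high_responder_amp_fc must be >= 1")
        if not 0 <= int(self.seed) < 2**63:
            raise ConfigError("seed must be a non-negative 63-bit integer")

    @property
    def n_frames(self) -> int:
        """Frames per generated trace: round(window/dt) + 1."""
        return int(round(self.window_s / self.dt_s)) + 1

    def wave_rate(self, condition: str) -> float:
        from .core import CONTROL
        return self.wave_rate_control if condition == CONTROL else self.wave_rate_disuse

    def high_responder_frac(self, condition: str) -> float:
        from .core import CONTROL
        return (self.high_responder_frac_control if condition == CONTROL
                else self.high_responder_frac_disuse)

    def pmd_frac(self, condition: str) -> float:
        from .core import CONTROL
        return self.pmd_frac_control if condition == CONTROL else self.pmd_frac_disuse

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
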