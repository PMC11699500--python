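"""Simulation configuration for the synthetic wearable cohort.

The defaults encode the study conditions the pipeline is meant to emulate:
a cohort of 875 participants (59.3% female), sex-specific resting-heart-rate
marginals of 66.6 (SD 11.2) bpm for females and 64.4 (SD 12.3) bpm for males,
an inverted-U age profile, and a PPG artifact mechanism (false-beat splitting)
that produces a small positive device bias declining with the reference RHR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .exceptions import ConfigError

__all__ = ["SimulationConfig", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    # cohort composition
    n_participants: int = 875
    prop_female: float = 0.593
    age_range: tuple[float, float] = (18.0, 84.0)

    # latent resting-heart-rate marginals, bpm
    rhr_mean_female: float = 66.6
    rhr_sd_female: float = 11.2
    rhr_mean_male: float = 64.4
    rhr_sd_male: float = 12.3

    # inverted-U age profile: vertex location (years) and curvature (bpm/yr^2,
    # negative = inverted U)
    age_peak: float = 50.0
    age_curvature: float = -0.004

    # measurement layer
    ecg_noise_sd: float = 2.7  # bpm; ECG reference error
    hrv_sd: float = 30.0  # ms; beat-to-beat IBI jitter
    artifact_rate: float = 0.03  # per-beat probability of a false-beat split
    artifact_hr_coupling: float = 2.0  # >0: long IBIs split more often

    # clean device-error injection (parameter-recovery knobs); the additive
    # offset and the difference-vs-ECG slope are applied to the latent device
    # RHR, centered at the configured cohort-mean RHR
    device_offset_bpm: float = 0.0
    device_slope: float = 0.0

    # gating streams
    p_off_wrist: float = 0.03  # P(window contains an off-wrist state)
    p_active_epoch: float = 0.05  # background per-epoch activity probability
    p_induce_active: float = 0.0  # P(all window epochs active -> low-IBI)
    p_induce_low_ibi: float = 0.0  # P(sparse IBI stream -> low-IBI)

    # covariate layer
    covariate_effects: Mapping[str, float] | None = None  # name -> bpm slope
    missing_rate: float = 0.05  # MCAR cell-missingness fraction

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in (
            "prop_female",
            "artifact_rate",
            "p_off_wrist",
            "p_active_epoch",
            "p_induce_active",
            "p_induce_low_ibi",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        total_induced = self.p_off_wrist + self.p_induce_active + self.p_induce_low_ibi
        if total_induced > 1.0:
            raise ConfigError(
                "p_off_wrist + p_induce_active + p_induce_low_ibi must not exceed 1"
            )
        for name in ("rhr_sd_female", "rhr_sd_male"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("ecg_noise_sd", "hrv_sd", "artifact_hr_coupling"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must be (min, max) with min < max, got {self.age_range}")
        if self.rhr_mean_female <= 0 or self.rhr_mean_male <= 0:
            raise ConfigError("sex-specific RHR means must be > 0")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @property
    def rhr_mean_overall(self) -> float:
        """Configured cohort-mean RHR (slope-injection center)."""
        return (
            self.prop_female * self.rhr_mean_female
            + (1.0 - self.prop_female) * self.rhr_mean_male
        )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


_TUPLE_FIELDS = {"age_range"}
_INT_FIELDS = {"n_participants", "seed"}


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a flat ``key: value`` (or ``key=value``) text config file.

    Covariate effects are written as ``effect.<name>: <bpm slope>`` lines.
    Unknown keys raise :class:`ConfigError`.
    """
    kwargs: dict = {}
    effects: dict[str, float] = {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = ":" if ":" in line else "="
        if sep not in line:
            raise ConfigError(f"line {lineno}: expected 'key: value', got {raw!r}")
        key, value = (part.strip() for part in line.split(sep, 1))
        if key.startswith("effect."):
            effects[key[len("effect."):]] = float(value)
        elif key in _TUPLE_FIELDS:
            parts = [float(p) for p in value.replace(",", " ").split()]
            kwargs[key] = tuple(parts)
        elif key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in known:
            kwargs[key] = float(value)
        else:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
    if effects:
        kwargs["covariate_effects"] = effects
    return SimulationConfig(**kwargs)
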