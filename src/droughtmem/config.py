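"""Configuration objects for the priming-experiment simulator.

A :class:`PrimingSchedule` encodes the watering regime imposed on primed
plants: full irrigation up to flowering onset, then alternating total water
restriction and recovery periods.  The default schedule uses three
restrictions of increasing length (8, 11 and 14 days), each followed by a
14-day fully irrigated recovery, starting at 46 days after transplanting
(DAT); harvest falls at the end of the last recovery.

:class:`SimConfig` collects the design (accession and replicate counts,
measurement event counts) and the population distributions of the
biological parameters, including the accession-level stress-memory effects:
additive on the senescence slope, multiplicative on maximum foliar area,
minimum leaf-minus-air temperature and maximum 13C discrimination.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from ._errors import ConfigError

TREATMENTS = ("primed", "non_primed")


@dataclass(frozen=True)
class PrimingSchedule:
    restriction_lengths: tuple[int, ...] = (8, 11, 14)
    recovery_length: int = 14
    start_day: int = 46

    def validate(self) -> None:
        if not self.restriction_lengths:
            raise ConfigError("restriction_lengths", "must be non-empty")
        prev = 0
        for r in self.restriction_lengths:
            if r <= prev:
                raise ConfigError(
                    "restriction_lengths", "must be strictly increasing and positive"
                )
            prev = r
        if self.recovery_length <= 0:
            raise ConfigError("recovery_length", "must be > 0")
        if self.start_day < 0:
            raise ConfigError("start_day", "must be >= 0")

    @property
    def harvest_day(self) -> int:
        """Last day of the final recovery period (end of the experiment)."""
        return self.start_day + sum(self.restriction_lengths) + len(
            self.restriction_lengths
        ) * self.recovery_length

    def restriction_windows(self) -> list[tuple[int, int]]:
        """(start, end) DAT of each total-water-restriction period, end inclusive."""
        windows = []
        t = self.start_day
        for r in self.restriction_lengths:
            windows.append((t, t + r))
            t += r + self.recovery_length
        return windows

    def recovery_ends(self) -> list[int]:
        """DAT at which each recovery period ends (isotope sampling occasions)."""
        return [end + self.recovery_length for _, end in self.restriction_windows()]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise standard deviations, one per recorded variable."""

    spad: float = 1.5  # SPAD units
    foliar_area: float = 30.0  # cm^2
    leaf_temp: float = 0.5  # degC
    delta13c: float = 0.15  # permil
    biomass: float = 3.0  # g dry matter

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigError(f"measurement_noise.{name}", "sd must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(**{k: v * factor for k, v in asdict(self).items()})


@dataclass(frozen=True)
class SimConfig:
    n_accessions: int = 59
    n_replicates: int = 4
    schedule: PrimingSchedule = field(default_factory=PrimingSchedule)

    # chlorophyll trajectory: logistic rise to an accession peak, linear decline
    spad_peak_mean: float = 45.0
    spad_peak_sd: float = 3.0
    senescence_slope_mean: float = -0.25  # SPAD/day, non-primed
    senescence_slope_sd: float = 0.08
    memory_effect_S_mean: float = 0.12  # additive on the primed slope
    memory_effect_S_sd: float = 0.12

    # foliar area: logistic growth toward an accession maximum
    fa_max_mean: float = 700.0  # cm^2
    fa_max_sd: float = 250.0
    memory_ratio_FA_mean: float = 0.93
    memory_ratio_FA_sd: float = 0.10

    # leaf-minus-air temperature: seasonal curve with a scaled minimum
    dt_min_mean: float = -8.0  # degC
    dt_min_sd: float = 2.0
    memory_ratio_dT_mean: float = 0.94
    memory_ratio_dT_sd: float = 0.11

    # leaf 13C signature of the non-primed maximum-discrimination event
    delta13c_leaf_mean: float = -28.0  # permil
    delta13c_leaf_sd: float = 1.0
    memory_ratio_delta_mean: float = 1.00
    memory_ratio_delta_sd: float = 0.03

    # harvest biomass
    biomass_mean: float = 30.0  # g dry matter, non-primed
    biomass_sd: float = 12.0
    drought_reduction_mean: float = 0.30  # fractional loss under priming
    drought_reduction_sd: float = 0.15

    measurement_noise: NoiseModel = field(default_factory=NoiseModel)

    n_spad_events: int = 17
    n_temp_events: int = 14
    n_isotope_events: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_accessions", "n_replicates", "n_spad_events",
                     "n_temp_events", "n_isotope_events"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be >= 1")
        for name in ("spad_peak_sd", "senescence_slope_sd", "memory_effect_S_sd",
                     "fa_max_sd", "memory_ratio_FA_sd", "dt_min_sd",
                     "memory_ratio_dT_sd", "delta13c_leaf_sd",
                     "memory_ratio_delta_sd", "biomass_sd",
                     "drought_reduction_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "sd must be >= 0")
        if not (0.0 <= self.drought_reduction_mean < 1.0):
            raise ConfigError("drought_reduction_mean", "must be in [0, 1)")
        self.schedule.validate()
        self.measurement_noise.validate()

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], dict):
            sched = dict(d["schedule"])
            if "restriction_lengths" in sched:
                sched["restriction_lengths"] = tuple(sched["restriction_lengths"])
            d["schedule"] = PrimingSchedule(**sched)
        if "measurement_noise" in d and isinstance(d["measurement_noise"], dict):
            d["measurement_noise"] = NoiseModel(**d["measurement_noise"])
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError("<root>", str(exc)) from exc
        cfg.validate()
        return cfg
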