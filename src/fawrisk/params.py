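"""Species response parameters for the climatic niche engine.

The parameter set describes the thermal and soil-moisture response of the
fall armyworm: a trapezoidal temperature index between a lower development
threshold DV0 and an upper lethal threshold DV3 (optimal plateau DV1..DV2),
an analogous soil-moisture trapezoid SM0..SM3 (on a fraction-of-capacity
scale where values above 1 denote transient super-saturation), four weekly
stress accumulators (cold, heat, dry, wet) each with a threshold and a
weekly accumulation rate, a minimum annual degree-day sum PDD needed to
complete one generation, and the irrigation top-up applied in the irrigated
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SpeciesParameters:
    """Climatic response parameters of a species.

    Temperature thresholds are °C, stress rates week^-1 (cold/dry rates are
    negative by convention, mirroring the sign printed in CLIMEX parameter
    tables; only their magnitude enters the accumulation), PDD is in
    °C·days, irrigation_topup in mm·day^-1.
    """

    # temperature index (trapezoid)
    DV0: float = 9.4
    DV1: float = 26.0
    DV2: float = 30.0
    DV3: float = 39.5
    # moisture index (trapezoid, fraction of soil capacity)
    SM0: float = 0.1
    SM1: float = 0.65
    SM2: float = 1.5
    SM3: float = 2.0
    # cold stress (weekly Tmin below threshold)
    TTCS: float = 9.4
    THCS: float = -0.003
    # heat stress (weekly Tmax above threshold)
    TTHS: float = 39.5
    THHS: float = 0.005
    # dry stress (soil moisture below threshold)
    SMDS: float = 0.1
    HDS: float = -0.005
    # wet stress (soil moisture above threshold)
    SMWS: float = 2.0
    HWS: float = 0.01
    # minimum degree-day sum above DV0 for one generation
    PDD: float = 392.0
    # irrigation scenario top-up, mm/day
    irrigation_topup: float = 2.5

    def __post_init__(self) -> None:
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ValueError(
                f"temperature thresholds must satisfy DV0 < DV1 <= DV2 < DV3, "
                f"got {self.DV0}, {self.DV1}, {self.DV2}, {self.DV3}"
            )
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ValueError(
                f"moisture thresholds must satisfy SM0 < SM1 <= SM2 < SM3, "
                f"got {self.SM0}, {self.SM1}, {self.SM2}, {self.SM3}"
            )
        if self.THCS >= 0 or self.HDS >= 0:
            raise ValueError("cold/dry stress rates THCS and HDS must be negative")
        if self.THHS <= 0 or self.HWS <= 0:
            raise ValueError("heat/wet stress rates THHS and HWS must be positive")
        if self.PDD <= 0:
            raise ValueError("PDD must be positive")
        if self.irrigation_topup < 0:
            raise ValueError("irrigation top-up must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "SpeciesParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesParameters":
        """Load parameters from a flat YAML key-value file.

        Unknown keys are rejected so typos in a parameter name cannot
        silently fall back to a default.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in raw.items()})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: Default parameter set for *Spodoptera frugiperda*.
DEFAULT_PARAMETERS = SpeciesParameters()
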