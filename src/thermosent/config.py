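"""Pipeline configuration.

A single :class:`PipelineConfig` object drives every stage: which
reference window and percentile pair define "extreme", whether the
indices are clamped at zero, which time fixed effect enters the panel
models, and where inputs and outputs live.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class PipelineConfig:
    """Settings shared across pipeline stages.

    Parameters
    ----------
    reference_start, reference_end : int
        Inclusive year range of the climatological reference period used
        for the percentile thresholds (e.g. 2000-2019).
    study_year : int
        The year whose city-days form the estimation panel.  Must follow
        the reference period.
    q_upper, q_lower : float
        Upper/lower percentile pair defining warm-day and cold-night
        standards; 0.95/0.05 by default, 0.90/0.10 as robustness.
    clamp : bool
        If True, index values are floored at zero (only exceedances kept);
        the default keeps the signed, continuous index.
    window : int
        Half-width in days of the calendar-day pooling window for
        thresholds (0 = exactly the same day-of-year across years).
    fe_time : str
        Time fixed effect: ``"dow"`` (day-of-week dummies), ``"solar"``
        (24 solar terms) or ``"none"``.
    cluster : str
        Column name used for clustered standard errors.
    standardize_targets : list of str
        Regressor columns z-scored over the estimation sample.
    seed : int
        Seed for every random draw in a simulated run.
    paths : dict
        Named input/output locations (free-form, consumed by the CLI).
    """

    reference_start: int = 2000
    reference_end: int = 2019
    study_year: int = 2020
    q_upper: float = 0.95
    q_lower: float = 0.05
    clamp: bool = False
    window: int = 0
    fe_time: str = "dow"
    cluster: str = "city_id"
    standardize_targets: list[str] = field(default_factory=lambda: ["EHT", "ELT"])
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_end < self.reference_start:
            raise ConfigError("reference_end precedes reference_start")
        if not self.reference_end < self.study_year:
            raise ConfigError("reference period must end before the study year")
        if not (0.0 < self.q_lower < 0.5 < self.q_upper < 1.0):
            raise ConfigError(
                f"quantile pair must satisfy upper > 0.5 > lower, got "
                f"({self.q_upper}, {self.q_lower})"
            )
        if self.fe_time not in ("dow", "solar", "none", "week_of_year"):
            raise ConfigError(f"unknown fe_time {self.fe_time!r}")
        if self.window < 0:
            raise ConfigError("window must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hash of the configuration, used in run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
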