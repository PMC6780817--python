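"""Analysis configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import DomainError


@dataclass
class AnalysisConfig:
    """Knobs shared across the pipeline.

    ``clip_eps`` bounds affected fractions away from 0 and 1 before
    log-linearisation; ``additivity_band`` is the CI interval labelled
    additive; ``fa_levels`` are the inhibition levels reported;
    ``rounding`` sets the equipotent-ratio rule.
    """

    clip_eps: float = 0.005
    clip_policy: str = "keep"  # or "exclude"
    additivity_band: tuple[float, float] = (0.90, 1.10)
    fa_levels: tuple[float, ...] = (0.50, 0.75, 0.90, 0.95)
    rounding: str = "tens_half_up"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.clip_eps < 0.5:
            raise DomainError("clip_eps must lie in (0, 0.5)")
        if self.clip_policy not in ("keep", "exclude"):
            raise DomainError(f"unknown clip_policy {self.clip_policy!r}")
        low, high = self.additivity_band
        if not 0 < low <= high:
            raise DomainError("additivity_band must satisfy 0 < low <= high")
        self.additivity_band = (float(low), float(high))
        if len(self.fa_levels) == 0:
            raise DomainError("fa_levels must be non-empty")
        if any(not 0 < fa < 1 for fa in self.fa_levels):
            raise DomainError("fa_levels must lie strictly inside (0, 1)")
        self.fa_levels = tuple(float(f) for f in self.fa_levels)
        if self.rounding not in ("tens_half_up", "nearest_int"):
            raise DomainError(f"unknown rounding rule {self.rounding!r}")
        logging.getLogger("drugcombo").setLevel(self.log_level)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise DomainError("config file must contain a mapping")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
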