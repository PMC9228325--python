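"""Tabular record types exchanged between the pipeline stages.

All lengths are metres, areas m^2, volumes m^3, masses kg, ages days.
Missing trait values are represented as ``None`` (a poor mesh may still
yield some linear traits while volume or surface area are unmeasurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass
class TraitRecord:
    """One animal-visit measurement set from a body mesh."""

    animal_id: str
    age: float
    hg: float | None = None
    wh: float | None = None
    cd: float | None = None
    hw: float | None = None
    kw: float | None = None
    bsa: float | None = None
    volume: float | None = None
    quality: int = 4

    TRAITS = ("hg", "wh", "cd", "hw", "kw", "bsa", "volume")

    def __post_init__(self) -> None:
        if self.quality not in (1, 2, 3, 4):
            raise ValueError(f"quality must be 1-4, got {self.quality}")
        for name in self.TRAITS:
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if math.isnan(v):
                    v = None
                elif v <= 0:
                    raise ValueError(f"{name} must be positive, got {v}")
                setattr(self, name, v)
        if self.cd is not None and self.wh is not None and self.cd >= self.wh:
            raise ValueError("chest depth must be smaller than withers height")

    def get(self, name: str) -> float | None:
        if name not in self.TRAITS:
            raise KeyError(f"unknown trait {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class WeighRecord:
    """One animal-visit scale measurement."""

    animal_id: str
    age: float
    bw: float
    interpolated: bool = False

    def __post_init__(self) -> None:
        self.bw = float(self.bw)
        self.age = float(self.age)
        if self.bw <= 0:
            raise ValueError(f"body weight must be positive, got {self.bw}")


@dataclass
class GrowthSummary:
    """Per-stage mean and sample SD of the measured traits (n-1 denominator)."""

    stage: str
    mean_age: float
    n: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
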