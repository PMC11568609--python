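"""Run configuration: a single JSON-serializable settings object.

The config collects every knob the pipeline commands share — pixel scale,
segmentation threshold band, the white standard for ΔE1, an optional NO-S
Lab baseline for ΔE2, and the seed — and round-trips through JSON
unchanged.  Output CSVs are stamped with the config's SHA-256 hash so a
result can always be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    pixel_scale: float = 0.1  # mm per pixel
    threshold_low: int = 135
    threshold_high: int = 240
    white_standard: tuple[float, float, float] = (100.0, 0.0, 0.0)
    baseline_lab: tuple[float, float, float] | None = None  # NO-S mean for ΔE2
    seed: int = 0

    def __post_init__(self):
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if not (0 <= self.threshold_low <= self.threshold_high <= 255):
            raise ValueError("threshold band must satisfy 0 <= low <= high <= 255")
        if not (0.0 <= self.white_standard[0] <= 100.0):
            raise ValueError("white standard L* must lie in [0, 100]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["white_standard"] = list(self.white_standard)
        if self.baseline_lab is not None:
            d["baseline_lab"] = list(self.baseline_lab)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "white_standard" in d:
            d["white_standard"] = tuple(d["white_standard"])
        if d.get("baseline_lab") is not None:
            d["baseline_lab"] = tuple(d["baseline_lab"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form, for output provenance."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()
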