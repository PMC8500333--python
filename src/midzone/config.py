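"""Run configuration: a strict YAML-backed container of module parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SpindleSimConfig

_ALLOWED_SECTIONS = {
    "kymo": {"line_width_um", "threshold_frac", "sustain_frames",
             "grid_step_um", "outer_frac"},
    "frap": {"bleach_correct", "error_kind", "window_limit_factor"},
    "comets": {"min_frames", "bins", "internal_fraction"},
}


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``simulate`` holds :class:`SpindleSimConfig` fields; the other sections
    hold per-module parameter overrides.  Unknown keys anywhere are
    rejected so a typo cannot silently fall back to a default.
    """

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    kymo: dict = field(default_factory=dict)
    frap: dict = field(default_factory=dict)
    comets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # SpindleSimConfig.from_dict validates the simulate section
        if self.simulate:
            SpindleSimConfig.from_dict({**self.simulate})
        for section, allowed in _ALLOWED_SECTIONS.items():
            extra = set(getattr(self, section)) - allowed
            if extra:
                raise ValueError(
                    f"unknown keys in section {section!r}: {sorted(extra)}"
                )

    def sim_config(self, seed: int | None = None) -> SpindleSimConfig:
        d = dict(self.simulate)
        if seed is not None:
            d["seed"] = seed
        return SpindleSimConfig.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(d)
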