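"""Run configuration: thresholds in force for a CLI invocation.

Config files are plain ``key = value`` text (``#`` comments allowed).  Keys
matching the seven check limits configure scoring; the remaining keys tune
geometry and interpretation thresholds.  CLI flags override file values, and
every report embeds the effective configuration so a run is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .quality import CheckLimits
from .stereochem import RadiiTable

__all__ = ["RunConfig", "parse_config_file"]


def parse_config_file(path: str | Path) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        values[key.strip()] = value.strip()
    return values


@dataclass
class RunConfig:
    limits: CheckLimits = field(default_factory=CheckLimits)
    radii: RadiiTable = field(default_factory=RadiiTable)
    site_radius: float = 4.5
    clash_threshold: float = 0.4
    polder_margin: float = 0.05
    polder_floor: float = 0.8
    flag_ratio: float = 1.5
    grid_spacing: float = 0.2
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("site_radius", "clash_threshold", "flag_ratio", "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    _SCALARS = (
        "site_radius",
        "clash_threshold",
        "polder_margin",
        "polder_floor",
        "flag_ratio",
        "grid_spacing",
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values = parse_config_file(path)
        limit_names = {f.name for f in fields(CheckLimits)}
        limits = CheckLimits.from_mapping({k: v for k, v in values.items() if k in limit_names})
        kwargs = {k: float(v) for k, v in values.items() if k in cls._SCALARS}
        unknown = set(values) - limit_names - set(cls._SCALARS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(limits=limits, **kwargs)

    def describe(self) -> list[str]:
        lines = [f"site_radius={self.site_radius}", f"clash_threshold={self.clash_threshold}"]
        lines += [f"{f.name}={getattr(self.limits, f.name)}" for f in fields(CheckLimits)]
        lines += [
            f"polder_margin={self.polder_margin}",
            f"polder_floor={self.polder_floor}",
            f"flag_ratio={self.flag_ratio}",
            f"grid_spacing={self.grid_spacing}",
        ]
        return lines
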