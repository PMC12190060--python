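"""Run configuration: one YAML document drives a whole pipeline run.

Every threshold the analysis uses is explicit here — the SI optimal-range
level (0.6), the accuracy band (0.3), the grade edges (0.25/0.5/0.75), the
scenario deltas and the single integer seed that controls all randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grids import GridSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    lon_min: float = 109.0
    lon_max: float = 117.0
    lat_min: float = 6.0
    lat_max: float = 12.0
    base_cell_size: float = 0.1
    schemes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    count_mode: str = "distinct"
    bin_widths: dict = field(
        default_factory=lambda: {"sst": 0.2, "ssta": 0.1, "chl": 0.01}
    )
    si_range_threshold: float = 0.6
    accuracy_band: float = 0.3
    grade_edges: tuple[float, float, float] = (0.25, 0.5, 0.75)
    scenario_deltas: tuple[float, ...] = (0.0, 0.2, 0.5, 1.0, -0.2, -0.5, -1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.si_range_threshold <= 1.0:
            raise ValueError("si_range_threshold must be in (0, 1]")
        if not 0.0 < self.accuracy_band <= 1.0:
            raise ValueError("accuracy_band must be in (0, 1]")
        edges = tuple(self.grade_edges)
        if len(edges) != 3 or not all(0 < e < 1 for e in edges) or sorted(edges) != list(edges):
            raise ValueError("grade_edges must be three increasing values in (0, 1)")
        bad = [s for s in self.schemes if s not in range(1, 7)]
        if bad:
            raise ValueError(f"unknown scheme ids: {bad}")
        if self.count_mode not in ("distinct", "vessel_days"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        self.grid  # validate bounds/cell size

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.lon_min, self.lon_max, self.lat_min, self.lat_max, self.base_cell_size
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        d["grade_edges"] = list(self.grade_edges)
        d["scenario_deltas"] = list(self.scenario_deltas)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("schemes", "grade_edges", "scenario_deltas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
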