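"""Load-case description: reference-point loads, muscle loads, supports.

A load case is fully declarative: it names mesh sets and carries forces in
newtons, spring stiffnesses in N/mm and the incremental load schedule as
fractions of the total load.  It round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["PointLoad", "MuscleLoad", "SpringSupport", "LoadCase"]


@dataclass
class PointLoad:
    """Force at a reference point, distributed-coupled onto a surface set."""

    reference_point: tuple[float, float, float]  # mm
    force: tuple[float, float, float]  # N
    surface_set: str  # node-set name of the coupled patch


@dataclass
class MuscleLoad:
    """Resultant muscle force applied over an attachment node set."""

    attachment_set: str
    force: tuple[float, float, float]  # N


@dataclass
class SpringSupport:
    """Grounded springs on a node set; total patch stiffness per axis, N/mm."""

    node_set: str
    stiffness: float

    def __post_init__(self):
        if self.stiffness <= 0:
            raise ValueError("spring stiffness must be positive")


@dataclass
class LoadCase:
    name: str = "case"
    point_loads: list[PointLoad] = field(default_factory=list)
    muscle_loads: list[MuscleLoad] = field(default_factory=list)
    fixed_sets: list[str] = field(default_factory=list)
    springs: list[SpringSupport] = field(default_factory=list)
    initial_increment: float = 0.05  # fraction of total load
    max_increment: float = 0.1

    def __post_init__(self):
        if not (0 < self.initial_increment <= 1 and 0 < self.max_increment <= 1):
            raise ValueError("load increments must lie in (0, 1]")

    def referenced_sets(self) -> set[str]:
        out = set(self.fixed_sets)
        out |= {p.surface_set for p in self.point_loads}
        out |= {m.attachment_set for m in self.muscle_loads}
        out |= {s.node_set for s in self.springs}
        return out

    def validate_against(self, mesh) -> None:
        missing = [s for s in self.referenced_sets() if s not in mesh.node_sets]
        if missing:
            raise ValueError(f"load case references unknown node sets: {missing}")

    def total_applied_force(self) -> np.ndarray:
        f = np.zeros(3)
        for p in self.point_loads:
            f += np.asarray(p.force, dtype=float)
        for m in self.muscle_loads:
            f += np.asarray(m.force, dtype=float)
        return f

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "LoadCase":
        d = dict(d)
        d["point_loads"] = [
            PointLoad(tuple(p["reference_point"]), tuple(p["force"]), p["surface_set"])
            for p in d.get("point_loads", [])
        ]
        d["muscle_loads"] = [
            MuscleLoad(m["attachment_set"], tuple(m["force"]))
            for m in d.get("muscle_loads", [])
        ]
        d["springs"] = [
            SpringSupport(s["node_set"], float(s["stiffness"])) for s in d.get("springs", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "LoadCase":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
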