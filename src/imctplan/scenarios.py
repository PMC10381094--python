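"""Error-scenario sets for robust optimization and robustness evaluation.

A scenario combines a multiplicative range-scaling factor ``rho`` (a range
error of +-r% maps to rho = 1 -+ ... strictly, rho = 1 + r/100 scales every
water-equivalent path length) with a rigid isocenter shift in mm. Axis
convention: x = left-right (LR), y = anteroposterior (AP),
z = superoinferior (SI).

Two canonical sets are generated:

* the 14-scenario optimization set used by the voxel-wise worst-case
  planner: both range extremes crossed with the nominal position and single
  -axis +-s shifts (7 shift states per range), and
* the 28-scenario evaluation set: both range extremes crossed with 14 shift
  combinations per range -- the 6 single-axis moves plus the 8 full-corner
  (+-s, +-s, +-s) moves. Every evaluation shift has max-norm s; the nominal
  position is reported separately, not as a member of the evaluation set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Scenario",
    "nominal_scenario",
    "wc_optimization_scenarios",
    "evaluation_scenarios",
    "scenarios_to_json",
    "scenarios_from_json",
]

MAX_SHIFT_MM = 10.0


@dataclass(frozen=True)
class Scenario:
    id: str
    rho: float = 1.0
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tag: str = "nominal"

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("range scale rho must be positive")
        if any(abs(c) > MAX_SHIFT_MM for c in self.shift):
            raise ValueError(f"shift components must be within {MAX_SHIFT_MM} mm")

    @property
    def is_nominal(self) -> bool:
        return self.rho == 1.0 and all(c == 0.0 for c in self.shift)


def nominal_scenario() -> Scenario:
    return Scenario(id="nominal", rho=1.0, shift=(0.0, 0.0, 0.0), tag="nominal")


def _label(rho: float, shift: tuple[float, float, float]) -> str:
    parts = [f"rho{(rho - 1) * 100:+.1f}%"]
    for axis, c in zip("xyz", shift):
        if c != 0:
            parts.append(f"{axis}{c:+g}")
    if all(c == 0 for c in shift):
        parts.append("noshift")
    return "_".join(parts)


def _dedupe(pairs: Iterable[tuple[float, tuple[float, float, float]]],
            tag: str) -> list[Scenario]:
    seen: dict[tuple, Scenario] = {}
    for rho, shift in pairs:
        key = (round(rho, 12), tuple(round(c, 9) for c in shift))
        if key not in seen:
            seen[key] = Scenario(id=_label(rho, shift), rho=rho, shift=shift, tag=tag)
    return list(seen.values())


def _single_axis(s: float) -> list[tuple[float, float, float]]:
    out = []
    for axis in range(3):
        for sign in (+1.0, -1.0):
            shift = [0.0, 0.0, 0.0]
            shift[axis] = sign * s
            out.append(tuple(shift))
    return out


def wc_optimization_scenarios(range_pct: float = 3.5,
                              shift_mm: float = 2.0) -> list[Scenario]:
    """Both range extremes x {nominal, +-s on each axis}: 2 x 7 = 14."""
    if range_pct <= 0 or shift_mm <= 0:
        raise ValueError("range_pct and shift_mm must be positive")
    r = range_pct / 100.0
    shifts = [(0.0, 0.0, 0.0)] + _single_axis(shift_mm)
    return _dedupe(
        ((rho, sh) for rho in (1.0 - r, 1.0 + r) for sh in shifts),
        tag="optimization",
    )


def evaluation_scenarios(range_pct: float = 3.5,
                         shift_mm: float = 2.0) -> list[Scenario]:
    """Both range extremes x {6 single-axis, 8 corner} shifts: 2 x 14 = 28."""
    if range_pct < 0 or shift_mm <= 0:
        raise ValueError("shift_mm must be positive and range_pct nonnegative")
    r = range_pct / 100.0
    shifts = _single_axis(shift_mm) + [
        (sx * shift_mm, sy * shift_mm, sz * shift_mm)
        for sx in (+1.0, -1.0) for sy in (+1.0, -1.0) for sz in (+1.0, -1.0)
    ]
    return _dedupe(
        ((rho, sh) for rho in (1.0 - r, 1.0 + r) for sh in shifts),
        tag="evaluation",
    )


def scenarios_to_json(scenarios: Sequence[Scenario], path: str | Path) -> None:
    doc = [
        {"id": s.id, "rho": s.rho, "shift": list(s.shift), "tag": s.tag}
        for s in scenarios
    ]
    Path(path).write_text(json.dumps(doc, indent=2))


def scenarios_from_json(path: str | Path) -> list[Scenario]:
    doc = json.loads(Path(path).read_text())
    return [
        Scenario(id=d["id"], rho=float(d["rho"]), shift=tuple(d["shift"]),
                 tag=d["tag"])
        for d in doc
    ]
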