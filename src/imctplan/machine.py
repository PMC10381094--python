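"""Synthetic carbon pencil-beam machine model and spot/energy-layer placement.

The machine model is a fully parameterized, analytic stand-in for a scanned
carbon-ion beamline: a Bragg-curve family D(z; R) (integral depth dose in
Gy mm^2/MU against water-equivalent depth z for nominal range R), a lateral
single-Gaussian spread sigma(z), a dose-averaged LET curve LET(z; R) rising
from an entrance plateau (~13 keV/um) to roughly ten times that at the peak,
and linear-quadratic-model tables alpha(LET), beta(LET) for HSG cells. The
magnitudes are documented engineering choices; no agreement with any real
beamline is claimed. All shape parameters live in one serializable document
so a measured beam library could be substituted curve for curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .phantoms import Phantom
    from .scenarios import Scenario

__all__ = [
    "MachineModel",
    "Spot",
    "FieldGeometry",
    "default_machine_model",
    "place_spots",
    "spots_to_csv",
    "spots_from_csv",
]

_DEFAULT_PARAMS: dict[str, float] = {
    # depth dose
    "peak_amp": 1.0,            # Gy mm^2 / MU at the Bragg peak
    "plateau_frac": 0.30,       # entrance dose relative to peak
    "plateau_rise": 0.40,       # fractional rise of the plateau toward the peak
    "plateau_power": 3.0,
    "straggle_base_mm": 1.0,    # Bragg-peak width sigma_R = base + slope * R
    "straggle_slope": 0.012,
    "tail_frac": 0.04,          # fragmentation tail just beyond the peak
    "tail_decay_mm": 6.0,
    # lateral spread sigma(z) = s0 + s1 z + s2 z^2  (mm, z in mm)
    "sigma0_mm": 2.5,
    "sigma1": 0.004,
    "sigma2": 1.2e-5,
    # dose-averaged LET (keV/um)
    "let_entrance": 13.0,
    "let_peak_factor": 10.0,
    "let_power": 8.0,
    "let_tail_level": 30.0,
    "let_tail_decay_mm": 3.0,
    # LQM tables alpha(LET), beta(LET)
    "alpha_floor": 0.10,        # 1/Gy
    "alpha_span": 1.35,
    "alpha_let_scale": 75.0,    # keV/um
    "beta_ref": 0.0615,         # 1/Gy^2
    "beta_drop": 0.35,
    "beta_let_scale": 120.0,
}


@dataclass
class MachineModel:
    """Analytic-but-tabulated carbon beam model.

    Depth curves are generated from ``params`` on demand and cached per
    nominal range; the LQM tables are sampled once on ``let_grid``.
    """

    params: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PARAMS))
    ranges_mm: np.ndarray = field(
        default_factory=lambda: np.arange(15.0, 200.0 + 0.5, 1.0)
    )
    depth_step_mm: float = 0.5
    let_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 201.0, 1.0))

    def __post_init__(self) -> None:
        self.ranges_mm = np.asarray(self.ranges_mm, dtype=float)
        self.let_grid = np.asarray(self.let_grid, dtype=float)
        self._curve_cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        p = self.params
        self.alpha_table = p["alpha_floor"] + p["alpha_span"] * (
            1.0 - np.exp(-self.let_grid / p["alpha_let_scale"])
        )
        self.beta_table = p["beta_ref"] * (
            1.0 - p["beta_drop"] * (1.0 - np.exp(-self.let_grid / p["beta_let_scale"]))
        )

    # -- continuous curve definitions -------------------------------------

    def _depth_dose(self, z: np.ndarray, R: float) -> np.ndarray:
        from scipy.special import erfc

        p = self.params
        sr = p["straggle_base_mm"] + p["straggle_slope"] * R
        u = z - R
        plateau = (
            p["plateau_frac"]
            * (1.0 + p["plateau_rise"] * np.clip(z / R, 0, 1) ** p["plateau_power"])
            * 0.5 * erfc(u / (np.sqrt(2.0) * sr))
        )
        peak = np.exp(-(u**2) / (2.0 * sr**2))
        tail = p["tail_frac"] * np.exp(-np.clip(u, 0, None) / p["tail_decay_mm"]) * (
            0.5 * erfc(-u / (np.sqrt(2.0) * sr))
        )
        return p["peak_amp"] * (plateau + peak + tail)

    def _let(self, z: np.ndarray, R: float) -> np.ndarray:
        p = self.params
        l0 = p["let_entrance"]
        lpk = l0 * p["let_peak_factor"]
        rising = l0 * (
            1.0 + (p["let_peak_factor"] - 1.0) * np.clip(z / R, 0, 1) ** p["let_power"]
        )
        falling = p["let_tail_level"] + (lpk - p["let_tail_level"]) * np.exp(
            -np.clip(z - R, 0, None) / p["let_tail_decay_mm"]
        )
        return np.where(z <= R, rising, falling)

    # -- public lookups ----------------------------------------------------

    def depth_curves(self, R: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(z, dose, LET) sampled from 0 to R + 25 mm for nominal range R."""
        R = float(R)
        if R not in self._curve_cache:
            z = np.arange(0.0, R + 25.0 + self.depth_step_mm, self.depth_step_mm)
            self._curve_cache[R] = (z, self._depth_dose(z, R), self._let(z, R))
        return self._curve_cache[R]

    def sigma(self, z_weq: np.ndarray | float, R: float | None = None) -> np.ndarray:
        p = self.params
        z = np.clip(np.asarray(z_weq, dtype=float), 0, None)
        return p["sigma0_mm"] + p["sigma1"] * z + p["sigma2"] * z**2

    def sigma_max(self, R: float) -> float:
        return float(self.sigma(R + 25.0))

    def alpha_of_let(self, let: np.ndarray) -> np.ndarray:
        return np.interp(let, self.let_grid, self.alpha_table)

    def beta_of_let(self, let: np.ndarray) -> np.ndarray:
        return np.interp(let, self.let_grid, self.beta_table)

    def bragg_peak_depth(self, R: float) -> float:
        z, d, _ = self.depth_curves(R)
        return float(z[int(np.argmax(d))])

    @property
    def max_range(self) -> float:
        return float(self.ranges_mm.max())

    def snap_range(self, R: float) -> float:
        """Nearest available nominal range."""
        return float(self.ranges_mm[int(np.argmin(np.abs(self.ranges_mm - R)))])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "ranges_mm": self.ranges_mm.tolist(),
            "depth_step_mm": self.depth_step_mm,
            "let_grid": self.let_grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MachineModel":
        return cls(
            params=dict(d["params"]),
            ranges_mm=np.asarray(d["ranges_mm"], dtype=float),
            depth_step_mm=float(d["depth_step_mm"]),
            let_grid=np.asarray(d["let_grid"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MachineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_machine_model() -> MachineModel:
    return MachineModel()


@dataclass(frozen=True)
class Spot:
    """One pencil beam: field id, nominal range, lateral position, MU weight."""

    field: int
    range_mm: float
    u_mm: float
    v_mm: float
    weight_mu: float = 1.0

    def __post_init__(self) -> None:
        if self.weight_mu < 0:
            raise ValueError("spot weight must be nonnegative")


@dataclass(frozen=True)
class FieldGeometry:
    """Beam port: direction unit vector plus the lateral frame at isocenter.

    ``port_deg`` rotates the source around the z (SI) axis in the axial
    plane (port 0 fires along -y, i.e. from the +y/anterior side; port 90
    from +x); ``couch_deg`` additionally rotates the patient around z.
    """

    port_deg: float = 0.0
    couch_deg: float = 0.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def direction(self) -> np.ndarray:
        theta = np.deg2rad(self.port_deg + self.couch_deg)
        d = np.array([-np.sin(theta), -np.cos(theta), 0.0])
        return d / np.linalg.norm(d)

    @property
    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u_hat, v_hat, d_hat) right-handed beam frame."""
        d = self.direction
        vref = np.array([0.0, 0.0, 1.0])
        if abs(float(d @ vref)) > 0.99:
            vref = np.array([1.0, 0.0, 0.0])
        u = np.cross(vref, d)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v, d


def place_spots(
    phantom: "Phantom",
    fields: Sequence[FieldGeometry],
    machine: MachineModel,
    target: str = "CTV",
    lateral_margin_mm: float = 0.0,
    layer_spacing_mm: float = 3.0,
    lateral_pitch_mm: float = 4.0,
    scenario_set: Sequence["Scenario"] | None = None,
) -> list[Spot]:
    """Place energy layers and lateral spot grids over the target.

    Per field, lateral positions form a regular grid covering the beam's-eye
    -view projection of the target plus ``lateral_margin_mm``; each position
    receives energy layers spanning the water-equivalent depth extent of the
    nearby target voxels (again widened by the margin). When a scenario set
    is supplied, coverage is the union of the shifted/range-scaled target
    footprints over all scenarios -- the automatic safety margin of the
    worst-case planner. Initial weights are uniform (1 MU).
    """
    from .influence import BevWepl

    tgt_idx = phantom.roi_indices(target)
    if tgt_idx.size == 0:
        raise ValueError(f"target ROI {target!r} is empty")
    pts = phantom.grid.voxel_centers()[tgt_idx]

    if scenario_set is None or len(scenario_set) == 0:
        scen_list: list[tuple[float, np.ndarray]] = [(1.0, np.zeros(3))]
    else:
        scen_list = [(s.rho, np.asarray(s.shift, dtype=float)) for s in scenario_set]

    half = lateral_pitch_mm / 2.0
    spots: list[Spot] = []
    for fid, fg in enumerate(fields):
        uh, vh, dh = fg.frame
        iso = np.asarray(fg.isocenter)
        bev = BevWepl(phantom, fg)
        rel = pts - iso
        u0 = rel @ uh
        v0 = rel @ vh
        z0 = rel @ dh
        # union of (u, v, wepl) target samples over scenarios
        us, vs, ws = [], [], []
        for rho, shift in scen_list:
            tu, tv = float(shift @ uh), float(shift @ vh)
            us.append(u0 + tu)
            vs.append(v0 + tv)
            ws.append(rho * bev.sample(u0 + tu, v0 + tv, z0))
        u = np.concatenate(us)
        v = np.concatenate(vs)
        w = np.concatenate(ws)

        wmax_needed = float(w.max()) + lateral_margin_mm
        if wmax_needed > machine.max_range:
            raise ValueError(
                f"target depth {wmax_needed:.1f} mm exceeds machine max range "
                f"{machine.max_range:.1f} mm"
            )

        gu = _lateral_axis(u, lateral_margin_mm, lateral_pitch_mm)
        gv = _lateral_axis(v, lateral_margin_mm, lateral_pitch_mm)
        reach = half + lateral_margin_mm + 1e-9
        order = np.argsort(u, kind="stable")
        u_s, v_s, w_s = u[order], v[order], w[order]
        for cu in gu:
            lo = np.searchsorted(u_s, cu - reach)
            hi = np.searchsorted(u_s, cu + reach)
            if hi <= lo:
                continue
            vv, ww = v_s[lo:hi], w_s[lo:hi]
            for cv in gv:
                sel = np.abs(vv - cv) <= reach
                if not sel.any():
                    continue
                wlo = float(ww[sel].min()) - lateral_margin_mm
                whi = float(ww[sel].max()) + lateral_margin_mm
                n_layers = max(int(np.ceil((whi - wlo) / layer_spacing_mm)) + 1, 1)
                layers = {
                    machine.snap_range(wlo + k * layer_spacing_mm)
                    for k in range(n_layers)
                }
                for R in sorted(layers):
                    spots.append(Spot(fid, R, float(cu), float(cv), 1.0))
    spots.sort(key=lambda s: (s.field, s.range_mm, s.u_mm, s.v_mm))
    return spots


def _lateral_axis(coords: np.ndarray, margin: float, pitch: float) -> np.ndarray:
    lo = float(coords.min()) - margin
    hi = float(coords.max()) + margin
    n = max(int(np.ceil((hi - lo) / pitch)) + 1, 1)
    center = (lo + hi) / 2.0
    return center + pitch * (np.arange(n) - (n - 1) / 2.0)


def spots_to_csv(spots: Sequence[Spot], path: str | Path) -> None:
    pd.DataFrame(
        [(s.field, s.range_mm, s.u_mm, s.v_mm, s.weight_mu) for s in spots],
        columns=["field", "range_mm", "u_mm", "v_mm", "weight_MU"],
    ).to_csv(path, index=False)


def spots_from_csv(path: str | Path) -> list[Spot]:
    df = pd.read_csv(path)
    return [
        Spot(int(r.field), float(r.range_mm), float(r.u_mm), float(r.v_mm),
             float(r.weight_MU))
        for r in df.itertuples(index=False)
    ]
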