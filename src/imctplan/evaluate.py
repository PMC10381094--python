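"""Plan evaluation: DVHs, scenario robustness indices and 3D local gamma.

Robustness follows the max-minus-min convention: a plan's D98 (target) and
Dmax (OAR) are recomputed for every scenario of the evaluation set with the
optimized spot weights held fixed; the robustness index is the spread
(max - min) of each DVH statistic over the examined scenarios, with doses
reported normalized to the prescription. The nominal volume is included in
the min/max envelope so the reported nominal value always lies inside it.

The gamma comparison uses local dose normalization: for each reference
voxel above the low-dose threshold,

    gamma(i) = min_o sqrt( (D_eval(p_i + o) - D_ref(p_i))^2
                           / (dd * D_ref(p_i))^2  +  |o|^2 / dta^2 ),

searched over a ball of offsets (default 3x the distance criterion) with
trilinear subvoxel interpolation of the evaluated volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .influence import DoseEngine
from .machine import Spot
from .rbe import PhotonLQM, biological_dose, clinical_dose, effect_from_components
from .scenarios import Scenario, nominal_scenario

__all__ = [
    "DVHCurve",
    "RobustnessReport",
    "GammaResult",
    "dvh",
    "dvh_from_samples",
    "robustness_report",
    "gamma_3d_local",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose: np.ndarray     # ascending dose axis (sample doses)
    volume: np.ndarray   # fraction of the structure receiving >= dose

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume) > 1e-12):
            raise ValueError("DVH volume must be nonincreasing in dose")

    def d_at(self, p: float) -> float:
        """Dose received by at least p% of the volume (linear interpolation)."""
        if not 0 < p <= 100:
            raise ValueError("p must be in (0, 100]")
        v = p / 100.0
        # volume is nonincreasing along dose; interpolate on reversed axes
        return float(np.interp(v, self.volume[::-1], self.dose[::-1]))

    @property
    def d98(self) -> float:
        return self.d_at(98.0)

    @property
    def dmax(self) -> float:
        return float(self.dose[-1])


def dvh_from_samples(doses: np.ndarray, structure: str = "") -> DVHCurve:
    d = np.sort(np.asarray(doses, dtype=float))
    if d.size == 0:
        raise ValueError("empty structure mask")
    n = d.size
    vol = (n - np.arange(n)) / n
    return DVHCurve(structure=structure, dose=d, volume=vol)


def dvh(dose_volume, mask: np.ndarray, structure: str = "") -> DVHCurve:
    """DVH of a dose volume (3D array or DoseVolume) over a boolean mask."""
    values = getattr(dose_volume, "values", dose_volume)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty structure mask")
    return dvh_from_samples(np.asarray(values)[m], structure=structure)


@dataclass
class RobustnessReport:
    """Per-structure scenario envelope of DVH statistics.

    ``table`` holds one row per (scenario, structure) with the normalized
    statistic; ``summary`` holds nominal / max / min / delta per structure.
    All doses are clinical, normalized to the prescription.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    prescription_gyrbe: float

    def stat(self, structure: str, which: str) -> float:
        row = self.summary.loc[self.summary.structure == structure]
        return float(row[which].iloc[0])


def robustness_report(
    engine: DoseEngine,
    spots: Sequence[Spot],
    x: np.ndarray,
    scenario_set: Sequence[Scenario],
    structures: dict[str, np.ndarray],
    prescription_gyrbe: float,
    lqm: PhotonLQM | None = None,
    metrics: dict[str, str] | None = None,
) -> RobustnessReport:
    """Recompute the clinical dose per scenario and report D98/Dmax spreads.

    ``structures`` maps structure name -> row positions in the engine's
    calculation-voxel list; ``metrics`` maps structure name -> "D98" or
    "Dmax" (default: D98 for CTV-like, Dmax for OAR-like names).
    """
    lqm = lqm or PhotonLQM()
    if metrics is None:
        metrics = {
            name: ("Dmax" if "OAR" in name.upper() else "D98")
            for name in structures
        }
    rows = []
    scen_list = [nominal_scenario()] + list(scenario_set)
    for scen in scen_list:
        d, a, b = engine.scenario_dab(spots, x, scen)
        e = effect_from_components(a, b, d)
        clin = clinical_dose(biological_dose(e, lqm), lqm)
        for name, rsel in structures.items():
            samples = clin[rsel] / prescription_gyrbe
            if metrics[name] == "D98":
                stat = dvh_from_samples(samples, name).d98
            else:
                stat = float(samples.max())
            rows.append(
                {"scenario": scen.id, "tag": scen.tag, "structure": name,
                 "metric": metrics[name], "value": stat}
            )
    table = pd.DataFrame(rows)
    summary_rows = []
    for name in structures:
        sub = table[table.structure == name]
        nom = float(sub[sub.tag == "nominal"].value.iloc[0])
        vmax = float(sub.value.max())
        vmin = float(sub.value.min())
        summary_rows.append(
            {"structure": name, "metric": metrics[name], "nominal": nom,
             "max": vmax, "min": vmin, "delta": vmax - vmin}
        )
    return RobustnessReport(
        table=table, summary=pd.DataFrame(summary_rows),
        prescription_gyrbe=prescription_gyrbe,
    )


@dataclass
class GammaResult:
    dta_mm: float
    dd_fraction: float
    threshold: float
    gamma: np.ndarray      # per-voxel gamma, NaN outside the analyzed region
    pass_rate: float       # percent of analyzed voxels with gamma <= 1

    @property
    def analyzed(self) -> np.ndarray:
        return ~np.isnan(self.gamma)


def gamma_3d_local(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing_mm: Sequence[float],
    dta_mm: float = 2.0,
    dd_percent: float = 3.0,
    threshold: float = 0.10,
    search_factor: float = 3.0,
    step_mm: float = 0.5,
) -> GammaResult:
    """3D gamma analysis with local dose normalization.

    ``reference`` and ``evaluated`` must share one grid (``spacing_mm``);
    resampling is out of scope. Voxels below ``threshold`` x max(reference)
    are excluded from the analysis.
    """
    ref = np.asarray(getattr(reference, "values", reference), dtype=float)
    ev = np.asarray(getattr(evaluated, "values", evaluated), dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("reference and evaluated volumes must share a grid")
    spacing = np.asarray(spacing_mm, dtype=float)
    dd = dd_percent / 100.0
    analyzed = ref >= threshold * ref.max()
    if not analyzed.any():
        raise ValueError("no voxel above the low-dose threshold")

    radius = search_factor * dta_mm
    ax = [np.arange(-radius, radius + step_mm / 2, step_mm) for _ in range(3)]
    ox, oy, oz = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    offs, dist = offs[order], dist[order]

    ref_a = ref[analyzed]
    denom = dd * ref_a
    best = np.full(ref_a.shape, np.inf)
    for o, r in zip(offs, dist):
        dterm2 = (r / dta_mm) ** 2
        if dterm2 >= float(best.max()):
            break  # offsets are distance-sorted; no voxel can improve
        shifted = ndimage.shift(ev, -o / spacing, order=1, mode="nearest")
        diff = (shifted[analyzed] - ref_a) / denom
        np.minimum(best, diff**2 + dterm2, out=best)
    gamma = np.full(ref.shape, np.nan)
    gamma[analyzed] = np.sqrt(best)
    pass_rate = 100.0 * float(np.mean(gamma[analyzed] <= 1.0 + 1e-6))
    return GammaResult(
        dta_mm=dta_mm, dd_fraction=dd, threshold=threshold,
        gamma=gamma, pass_rate=pass_rate,
    )
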