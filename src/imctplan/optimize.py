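"""Objective terms and solvers: conventional, spot-control (SC) and
voxel-wise worst-case (WC) robust radiobiological optimization.

All penalties act in biological-effect space so every term shares units.
The nominal term is a quadratic target deviation plus a one-sided OAR
overshoot,

    F_Dnom = sum_T w_T (e_i - e_presc)^2 + sum_O w_O max(0, e_i - e_max)^2.

The SC planner adds three spot-resolved penalties evaluated in the nominal
scenario only: a heterogeneity term K0 <m_j>_x (weight-weighted mean of a
per-spot lateral-WEPL density index), an in-field effect-gradient term
G0 sum_l sum_pairs ((e_{l,i} - e_{l,k}) / r_ik)^2 over ordered target voxel
pairs within Delta_r, and an OAR-sparing term <K1 P_R + K2 P_S>_x built
from geometric risk indices (exponential decay of the Bragg-peak / beam-path
distance to the OAR under the assumed range / setup errors).

The WC planner instead penalizes each voxel's own worst biological effect
over an explicit scenario list:

    F_WC = F_Dnom + p_w [ sum_T w_T ((min_s e_i^s - e_ref)^2
                                     + (max_s e_i^s - e_ref)^2)
                        + sum_O w_O theta(max_s e_i^s - e_max)
                                      (max_s e_i^s - e_max)^2 ],

with the argmin/argmax scenario per voxel frozen within each outer
iteration. ``e_ref`` defaults to the prescribed effect; the nominal-scenario
effect is available as a configuration switch.

Spot weights are minimized under x >= 0 with bound-constrained L-BFGS-B and
analytic gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize as sopt
from scipy.spatial import cKDTree

from .influence import DoseEngine, InfluenceSet
from .machine import Spot
from .phantoms import Phantom
from .scenarios import Scenario

log = logging.getLogger(__name__)

__all__ = [
    "NominalObjectiveConfig",
    "SCConfig",
    "WCConfig",
    "OptimizationResult",
    "Objective",
    "f_dnom",
    "f_hetero",
    "f_grad",
    "f_oar_sparing",
    "f_wc",
    "density_index",
    "risk_indices",
    "build_gradient_pairs",
    "initial_weights",
    "solve",
    "solve_wc",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class NominalObjectiveConfig:
    """Targets and weights of the nominal-dose objective, in effect space."""

    e_presc: float
    target_rows: np.ndarray
    oar_rows: np.ndarray
    e_max: float = 0.0
    w_target: float = 1.0
    w_oar: float = 1.0

    def __post_init__(self) -> None:
        if self.e_presc <= 0:
            raise ValueError("prescribed effect must be positive")
        if self.e_max < 0 or self.w_target < 0 or self.w_oar < 0:
            raise ValueError("weights and ceilings must be nonnegative")
        self.target_rows = np.asarray(self.target_rows)
        self.oar_rows = np.asarray(self.oar_rows)


@dataclass
class SCConfig:
    """Spot-control penalties (heterogeneity, gradient, OAR risk)."""

    k0: float = 0.0           # heterogeneity penalty
    k1: float = 0.0           # range-risk penalty
    k2: float = 0.0           # setup-risk penalty
    g0: float = 0.0           # in-field gradient penalty
    delta_r_mm: float = 6.0   # gradient neighborhood
    area_radius_mm: float = 5.0   # density-index sampling radius around the ray
    n_area_rays: int = 8
    range_pct: float = 3.5    # assumed range error for P_R
    shift_mm: float = 2.0     # assumed setup error for P_S
    lambda_r_mm: float = 5.0  # risk-index decay lengths
    lambda_s_mm: float = 5.0
    pair_cap: int = 50_000
    robust_scale: float = 1.0  # global multiplier on all SC penalties

    def __post_init__(self) -> None:
        if min(self.k0, self.k1, self.k2, self.g0) < 0:
            raise ValueError("penalty coefficients must be nonnegative")
        if self.delta_r_mm <= 0:
            raise ValueError("delta_r must be positive")


@dataclass
class WCConfig:
    """Worst-case importance and scenario list."""

    p_w: float = 1.0
    scenarios: Sequence[Scenario] = dc_field(default_factory=list)
    reference: str = "prescription"  # or "nominal"

    def __post_init__(self) -> None:
        if self.p_w < 0:
            raise ValueError("worst-case importance p_w must be nonnegative")
        if self.reference not in ("prescription", "nominal"):
            raise ValueError("reference must be 'prescription' or 'nominal'")


@dataclass
class OptimizationResult:
    x: np.ndarray
    trace: list[float]
    breakdown: dict[str, float]
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# Objective terms: each returns (value, gradient)
# ---------------------------------------------------------------------------


def f_dnom(x: np.ndarray, infl: InfluenceSet,
           cfg: NominalObjectiveConfig) -> tuple[float, np.ndarray]:
    """Quadratic target deviation + one-sided OAR overshoot in effect space."""
    x = np.asarray(x, dtype=float)
    d, a, b = infl.dab(x)
    e = a + b * d
    rt = e[cfg.target_rows] - cfg.e_presc
    ro = np.maximum(e[cfg.oar_rows] - cfg.e_max, 0.0)
    val = cfg.w_target * float(rt @ rt) + cfg.w_oar * float(ro @ ro)
    r = np.zeros_like(e)
    np.add.at(r, cfg.target_rows, 2.0 * cfg.w_target * rt)
    np.add.at(r, cfg.oar_rows, 2.0 * cfg.w_oar * ro)
    return val, infl.effect_vjp(r, d, b)


def _ratio_penalty(x: np.ndarray, cost: np.ndarray) -> tuple[float, np.ndarray]:
    """Weight-weighted mean of per-spot costs: (c.x)/(1.x); 0 at x = 0."""
    total = float(x.sum())
    if total <= 0:
        return 0.0, np.zeros_like(x)
    val = float(cost @ x) / total
    return val, (cost - val) / total


def f_hetero(x: np.ndarray, m: np.ndarray, k0: float) -> tuple[float, np.ndarray]:
    val, g = _ratio_penalty(np.asarray(x, dtype=float), k0 * np.asarray(m))
    return val, g


def f_oar_sparing(x: np.ndarray, p_r: np.ndarray, p_s: np.ndarray,
                  k1: float, k2: float) -> tuple[float, np.ndarray]:
    cost = k1 * np.asarray(p_r) + k2 * np.asarray(p_s)
    return _ratio_penalty(np.asarray(x, dtype=float), cost)


def build_gradient_pairs(points_mm: np.ndarray, delta_r_mm: float,
                         cap: int = 50_000, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Ordered target-voxel pairs within delta_r: (ii, kk, 1/r^2, scale).

    Unordered pairs are found with a KD-tree, seeded-subsampled to ``cap``
    if needed (``scale`` restores the full-sum magnitude), then mirrored so
    both orderings are counted.
    """
    tree = cKDTree(points_mm)
    pairs = tree.query_pairs(r=delta_r_mm, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    scale = 1.0
    if cap and len(pairs) > cap // 2:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=cap // 2, replace=False)
        scale = len(pairs) / (cap // 2)
        pairs = pairs[np.sort(keep)]
    ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
    kk = np.concatenate([pairs[:, 1], pairs[:, 0]])
    dr = points_mm[ii] - points_mm[kk]
    inv_r2 = 1.0 / np.einsum("ij,ij->i", dr, dr)
    return ii, kk, inv_r2, scale


def f_grad(x: np.ndarray, infl: InfluenceSet, target_rows: np.ndarray,
           pairs: tuple[np.ndarray, np.ndarray, np.ndarray, float],
           g0: float) -> tuple[float, np.ndarray]:
    """In-field effect-gradient suppression over ordered target voxel pairs.

    ``pairs`` indices refer to positions within ``target_rows``.
    """
    x = np.asarray(x, dtype=float)
    ii, kk, inv_r2, scale = pairs
    val = 0.0
    grad = np.zeros(infl.n_spots)
    for fid, (d_l, a_l, b_l) in infl.field_dab(x).items():
        e_l = (a_l + b_l * d_l)[target_rows]
        de = e_l[ii] - e_l[kk]
        val += float(de**2 @ inv_r2)
        r_t = np.zeros_like(e_l)
        np.add.at(r_t, ii, 2.0 * de * inv_r2)
        np.add.at(r_t, kk, -2.0 * de * inv_r2)
        r = np.zeros(len(d_l))
        np.add.at(r, target_rows, r_t)
        grad += infl.field_effect_vjp(fid, r, d_l, b_l)
    return g0 * scale * val, g0 * scale * grad


def density_index(spots: Sequence[Spot], engine: DoseEngine,
                  area_radius_mm: float = 5.0, n_rays: int = 8) -> np.ndarray:
    """Per-spot lateral-WEPL heterogeneity index m_j.

    For each spot, the WEPL of the central axis at the spot's range depth
    (= the nominal range R) is compared with the WEPL of ``n_rays`` parallel
    rays on a circle of ``area_radius_mm`` at the same geometric depth;
    m_j = sum of squared differences (mm^2).
    """
    ang = 2.0 * np.pi * np.arange(n_rays) / n_rays
    du = area_radius_mm * np.cos(ang)
    dv = area_radius_mm * np.sin(ang)
    m = np.zeros(len(spots))
    for j, s in enumerate(spots):
        bev = engine.bev[s.field]
        z_pk = bev.depth_at_wepl(s.u_mm, s.v_mm, s.range_mm)
        l_i = bev.sample(s.u_mm + du, s.v_mm + dv, np.full(n_rays, z_pk))
        m[j] = float(np.sum((s.range_mm - np.asarray(l_i)) ** 2))
    return m


def risk_indices(spots: Sequence[Spot], engine: DoseEngine, phantom: Phantom,
                 oar_name: str = "OAR", range_pct: float = 3.5,
                 shift_mm: float = 2.0, lambda_r_mm: float = 5.0,
                 lambda_s_mm: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Geometric risk indices (P_R, P_S) per spot.

    P_R = exp(-Delta_peak / lambda_R) with Delta_peak the smallest distance
    from the spot's Bragg-peak position under the nominal and +-range-error
    scenarios to the OAR; P_S = exp(-Delta_path / lambda_S) with Delta_path
    the smallest lateral distance from the (+-setup-shifted) beam axis,
    upstream of the peak, to the OAR. Distances are clipped at zero so a
    peak/path inside the OAR yields an index of exactly 1.
    """
    oar_mask = phantom.rois[oar_name]
    if not oar_mask.any():
        raise ValueError("OAR mask is empty")
    oar_pts = phantom.grid.voxel_centers()[np.flatnonzero(oar_mask.ravel())]
    tree = cKDTree(oar_pts)
    half_vox = 0.5 * float(np.linalg.norm(phantom.grid.spacing))
    r = range_pct / 100.0
    rhos = (1.0 - r, 1.0, 1.0 + r)
    lat_shifts = [(0.0, 0.0), (shift_mm, 0.0), (-shift_mm, 0.0),
                  (0.0, shift_mm), (0.0, -shift_mm)]
    p_r = np.zeros(len(spots))
    p_s = np.zeros(len(spots))
    oar_beam: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for j, s in enumerate(spots):
        fg = engine.fields[s.field]
        uh, vh, dh = fg.frame
        iso = np.asarray(fg.isocenter)
        if s.field not in oar_beam:
            rel = oar_pts - iso
            oar_beam[s.field] = (rel @ uh, rel @ vh, rel @ dh)
        ou, ov, oz = oar_beam[s.field]
        bev = engine.bev[s.field]
        # --- range risk: Bragg-peak positions under range scaling
        d_peak = np.inf
        z_pk_nom = None
        for rho in rhos:
            z_pk = bev.depth_at_wepl(s.u_mm, s.v_mm, s.range_mm / rho)
            if rho == 1.0:
                z_pk_nom = z_pk
            pk = iso + s.u_mm * uh + s.v_mm * vh + z_pk * dh
            d_peak = min(d_peak, float(tree.query(pk)[0]))
        p_r[j] = np.exp(-max(d_peak - half_vox, 0.0) / lambda_r_mm)
        # --- setup risk: lateral distance of the shifted axis to the OAR
        up = oz <= z_pk_nom + half_vox
        if up.any():
            d_path = min(
                float(np.hypot(ou[up] - (s.u_mm + su),
                               ov[up] - (s.v_mm + sv)).min())
                for su, sv in lat_shifts
            )
        else:
            d_path = np.inf
        p_s[j] = np.exp(-max(d_path - half_vox, 0.0) / lambda_s_mm)
    return p_r, p_s


def _wc_selection(e_stack: np.ndarray, target_rows: np.ndarray,
                  oar_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(argmin_s, argmax_s on target rows; argmax_s on OAR rows)."""
    et = e_stack[:, target_rows]
    eo = e_stack[:, oar_rows]
    return et.argmin(axis=0), et.argmax(axis=0), eo.argmax(axis=0)


def f_wc(
    x: np.ndarray,
    scenario_infls: Sequence[InfluenceSet],
    nom_infl: InfluenceSet,
    cfg: NominalObjectiveConfig,
    wc: WCConfig,
    frozen: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Voxel-wise worst-case objective F_Dnom + p_w F_Dw and its gradient.

    With ``frozen`` the per-voxel argmin/argmax scenario selection is taken
    as given (minimax smoothing within an outer iteration); otherwise it is
    recomputed from the current weights.
    """
    if len(scenario_infls) == 0:
        raise ValueError("worst-case objective needs a nonempty scenario list")
    x = np.asarray(x, dtype=float)
    val, grad = f_dnom(x, nom_infl, cfg)
    if wc.p_w == 0.0:
        return val, grad

    dabs = [infl.dab(x) for infl in scenario_infls]
    e_stack = np.stack([a + b * d for d, a, b in dabs])
    if wc.reference == "prescription":
        e_ref = np.full(len(cfg.target_rows), cfg.e_presc)
        d_n = a_n = b_n = None
    else:
        d_n, a_n, b_n = nom_infl.dab(x)
        e_ref = (a_n + b_n * d_n)[cfg.target_rows]
    sel_min, sel_max, sel_oar = (
        frozen if frozen is not None
        else _wc_selection(e_stack, cfg.target_rows, cfg.oar_rows)
    )
    e_min = e_stack[sel_min, cfg.target_rows]
    e_max = e_stack[sel_max, cfg.target_rows]
    e_oar = e_stack[sel_oar, cfg.oar_rows]
    r_min = e_min - e_ref
    r_max = e_max - e_ref
    r_oar = np.maximum(e_oar - cfg.e_max, 0.0)
    fdw = (
        cfg.w_target * float(r_min @ r_min + r_max @ r_max)
        + cfg.w_oar * float(r_oar @ r_oar)
    )
    val += wc.p_w * fdw

    nrows = len(nom_infl.voxel_idx)
    for s, infl in enumerate(scenario_infls):
        r = np.zeros(nrows)
        mt = sel_min == s
        np.add.at(r, cfg.target_rows[mt], 2.0 * cfg.w_target * r_min[mt])
        mt = sel_max == s
        np.add.at(r, cfg.target_rows[mt], 2.0 * cfg.w_target * r_max[mt])
        mo = sel_oar == s
        np.add.at(r, np.asarray(cfg.oar_rows)[mo], 2.0 * cfg.w_oar * r_oar[mo])
        if np.any(r):
            d_s, _, b_s = dabs[s]
            grad += wc.p_w * infl.effect_vjp(r, d_s, b_s)
    if wc.reference == "nominal":
        r_n = np.zeros(nrows)
        np.add.at(r_n, cfg.target_rows,
                  -2.0 * cfg.w_target * (r_min + r_max))
        grad += wc.p_w * nom_infl.effect_vjp(r_n, d_n, b_n)
    return val, grad


# ---------------------------------------------------------------------------
# Objective bundles and solvers
# ---------------------------------------------------------------------------


class Objective:
    """Named sum of (value, gradient) terms."""

    def __init__(self, terms: dict[str, Callable[[np.ndarray],
                                                 tuple[float, np.ndarray]]]):
        self.terms = terms

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros_like(np.asarray(x, dtype=float))
        for fn in self.terms.values():
            v, g = fn(x)
            total += v
            grad += g
        return total, grad

    def breakdown(self, x: np.ndarray) -> dict[str, float]:
        return {name: fn(x)[0] for name, fn in self.terms.items()}


def initial_weights(infl: InfluenceSet, target_rows: np.ndarray,
                    e_presc: float) -> np.ndarray:
    """Uniform weights scaled so the mean target effect hits e_presc."""
    ones = np.ones(infl.n_spots)
    d, a, b = infl.dab(ones)
    am = float(np.mean(a[target_rows]))
    bm = float(np.mean((b * d)[target_rows]))
    if am <= 0 and bm <= 0:
        raise ValueError("no spot influences the target")
    s = (np.sqrt(am**2 + 4.0 * bm * e_presc) - am) / (2.0 * bm) if bm > 0 \
        else e_presc / am
    return np.full(infl.n_spots, s)


def solve(objective: Objective | Callable, x0: np.ndarray,
          max_iter: int = 300, ftol: float = 1e-6) -> OptimizationResult:
    """Bound-constrained (x >= 0) L-BFGS-B with per-iteration trace."""
    x0 = np.asarray(x0, dtype=float)
    fun = objective if callable(objective) else objective.__call__
    trace: list[float] = []

    def wrapped(x):
        v, g = fun(x)
        if not np.isfinite(v) or not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite objective or gradient")
        return v, g

    def cb(xk):
        v, _ = fun(xk)
        trace.append(float(v))
        if log.isEnabledFor(logging.DEBUG):
            if isinstance(objective, Objective):
                terms = " ".join(f"{k}={val:.6g}" for k, val
                                 in objective.breakdown(xk).items())
            else:
                terms = f"objective={v:.6g}"
            log.debug("iteration %d: %s", len(trace), terms)

    res = sopt.minimize(
        wrapped, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * len(x0),
        options={"maxiter": max_iter, "ftol": ftol},
        callback=cb,
    )
    breakdown = (
        objective.breakdown(res.x) if isinstance(objective, Objective)
        else {"objective": float(res.fun)}
    )
    return OptimizationResult(
        x=np.asarray(res.x), trace=[float(fun(x0)[0])] + trace,
        breakdown=breakdown, n_iter=int(res.nit), converged=bool(res.success),
    )


def solve_wc(
    scenario_infls: Sequence[InfluenceSet],
    nom_infl: InfluenceSet,
    cfg: NominalObjectiveConfig,
    wc: WCConfig,
    x0: np.ndarray,
    max_iter: int = 150,
    ftol: float = 1e-8,
) -> OptimizationResult:
    """Minimize the voxel-wise worst-case objective over x >= 0.

    The per-voxel argmin/argmax scenario selection is re-computed at every
    objective evaluation, so L-BFGS-B descends the true piecewise-smooth
    minimax objective with its subgradient.
    """
    if wc.p_w == 0.0:
        obj = Objective({"f_dnom": lambda x: f_dnom(x, nom_infl, cfg)})
        return solve(obj, x0, max_iter=max_iter, ftol=ftol)
    obj = Objective(
        {"f_wc": lambda x: f_wc(x, scenario_infls, nom_infl, cfg, wc)}
    )
    return solve(obj, x0, max_iter=max_iter, ftol=ftol)
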