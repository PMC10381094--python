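"""Spot-to-voxel dose influence: physical dose d_ij and LQM-weighted doses.

For every pencil-beam spot j and calculation voxel i the engine evaluates a
separable pencil-beam kernel

    d_ij = D(rho_s * w_i; R_j) * G2(u_i - u_j, v_i - v_j; sigma(w_i)),

where w_i is the voxel's own water-equivalent path length (WEPL) along the
field direction, rho_s the scenario range-scaling factor, D the integral
depth-dose curve of the spot's nominal range and G2 a normalized 2D
Gaussian truncated at ``kernel_cutoff_sigma``. The LQM-weighted entries are
alpha_ij d_ij and beta_ij d_ij with alpha_ij, beta_ij looked up from the
dose-averaged LET at the voxel's (scenario-scaled) depth.

Setup-error scenarios translate the phantom rigidly relative to the beams:
for a parallel beam only the lateral component matters, so the spot axes
are offset by the shift's in-plane projection while each voxel keeps the
WEPL of its own (unchanged) ray. Range scenarios scale WEPL
multiplicatively, which generalizes the +-3.5% relative range error to
heterogeneous media.

WEPL itself comes from a per-field beam's-eye-view resampling of the RSP
volume cumulated along the beam direction (parallel-beam geometry, source
at infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse

from .machine import FieldGeometry, MachineModel, Spot
from .phantoms import Phantom, VoxelGrid
from .scenarios import Scenario, nominal_scenario

__all__ = [
    "BevWepl",
    "InfluenceSet",
    "DoseVolume",
    "DoseEngine",
    "compute_influence",
    "default_calc_voxels",
    "physical_dose",
    "save_influence",
    "load_influence",
]


class BevWepl:
    """Beam's-eye-view WEPL lookup for one field through one phantom.

    Builds a beam-aligned grid over the phantom bounding box, resamples RSP
    onto it (trilinear) and cumulates along the beam direction with the
    midpoint rule. ``sample`` then interpolates the cumulative volume at
    arbitrary beam-frame coordinates (u, v, z), with z measured from the
    isocenter along the beam.
    """

    def __init__(self, phantom: Phantom, field_geom: FieldGeometry,
                 step_mm: float | None = None, pad_mm: float = 6.0):
        self.pad_mm = pad_mm
        self.frame = field_geom.frame
        uh, vh, dh = self.frame
        iso = np.asarray(field_geom.isocenter, dtype=float)
        h = step_mm if step_mm is not None else float(min(phantom.grid.spacing))
        lo, hi = phantom.grid.extent()
        corners = np.array(
            [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1])
             for c in (lo[2], hi[2])]
        ) - iso
        basis = np.stack([uh, vh, dh], axis=1)
        beam_c = corners @ basis
        b_lo = beam_c.min(axis=0) - pad_mm
        b_hi = beam_c.max(axis=0) + pad_mm
        axes = [np.arange(b_lo[k], b_hi[k] + h, h) for k in range(3)]
        self._origin = np.array([a[0] for a in axes])
        self._h = h
        # midpoint rule along the beam: exact for material boundaries on
        # voxel faces, half-step accurate otherwise
        zmid = axes[2][:-1] + h / 2.0
        gu, gv, gz = np.meshgrid(axes[0], axes[1], zmid, indexing="ij")
        pts = (
            iso[None, :]
            + gu.ravel()[:, None] * uh
            + gv.ravel()[:, None] * vh
            + gz.ravel()[:, None] * dh
        )
        from .phantoms import _sample_rsp

        rsp = _sample_rsp(phantom, pts).reshape(gu.shape)
        wepl = np.zeros(rsp.shape[:2] + (len(axes[2]),))
        np.cumsum(rsp * h, axis=2, out=wepl[..., 1:])
        self.wepl = wepl.astype(np.float32)
        self._zaxis = axes[2]
        self._col_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}

    def sample(self, u: np.ndarray, v: np.ndarray, z: np.ndarray) -> np.ndarray:
        coords = np.stack(
            [
                (np.asarray(u, dtype=float) - self._origin[0]) / self._h,
                (np.asarray(v, dtype=float) - self._origin[1]) / self._h,
                (np.asarray(z, dtype=float) - self._origin[2]) / self._h,
            ]
        )
        return ndimage.map_coordinates(self.wepl, coords, order=1, mode="nearest")

    def column(self, u0: float, v0: float) -> tuple[np.ndarray, np.ndarray]:
        """(z, WEPL(z)) along the axis at lateral position (u0, v0); cached."""
        key = (round(float(u0), 6), round(float(v0), 6))
        if key not in self._col_cache:
            z = self._zaxis
            w = self.sample(np.full_like(z, u0), np.full_like(z, v0), z)
            self._col_cache[key] = (z, np.asarray(w, dtype=float))
        return self._col_cache[key]

    def depth_at_wepl(self, u0: float, v0: float, wepl: float) -> float:
        """Geometric beam-frame z where the column WEPL reaches ``wepl``."""
        z, w = self.column(u0, v0)
        w = np.maximum.accumulate(w)  # guard against flat interpolation noise
        return float(np.interp(wepl, w, z))


@dataclass
class DoseVolume:
    """Physical dose on the full voxel grid (Gy)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.dims:
            raise ValueError("dose shape does not match grid dims")
        if np.any(self.values < 0):
            raise ValueError("dose must be nonnegative")


@dataclass
class InfluenceSet:
    """Per-field sparse influence matrices for one error scenario.

    Rows index ``voxel_idx`` (linear grid indices of the calculation
    voxels); columns index the spot list, partitioned per field by
    ``field_cols`` slices.
    """

    scenario: Scenario
    grid: VoxelGrid | None
    voxel_idx: np.ndarray
    spots: list[Spot]
    per_field: dict[int, tuple[sparse.csc_matrix, sparse.csc_matrix, sparse.csc_matrix]]
    field_cols: dict[int, np.ndarray] = dc_field(default_factory=dict)

    @classmethod
    def from_matrices(cls, D, A, B, scenario: Scenario | None = None,
                      voxel_idx: np.ndarray | None = None,
                      spots: list[Spot] | None = None) -> "InfluenceSet":
        """Single-field set from dense or sparse matrices (testing/toys)."""
        D = sparse.csc_matrix(D)
        A = sparse.csc_matrix(A)
        B = sparse.csc_matrix(B)
        n = D.shape[1]
        return cls(
            scenario=scenario or nominal_scenario(),
            grid=None,
            voxel_idx=voxel_idx if voxel_idx is not None
            else np.arange(D.shape[0]),
            spots=spots or [Spot(0, 100.0, 0.0, 0.0, 1.0) for _ in range(n)],
            per_field={0: (D, A, B)},
            field_cols={0: np.arange(n)},
        )

    @property
    def n_spots(self) -> int:
        return sum(len(c) for c in self.field_cols.values())

    def dab(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Total (d_i, a_i, b_i) = (D x, A x, B x) summed over fields."""
        x = np.asarray(x, dtype=float)
        n = len(self.voxel_idx)
        d = np.zeros(n)
        a = np.zeros(n)
        b = np.zeros(n)
        for fid, (D, A, B) in self.per_field.items():
            xl = x[self.field_cols[fid]]
            d += D @ xl
            a += A @ xl
            b += B @ xl
        return d, a, b

    def field_dab(self, x: np.ndarray) -> dict[int, tuple[np.ndarray, ...]]:
        x = np.asarray(x, dtype=float)
        out = {}
        for fid, (D, A, B) in self.per_field.items():
            xl = x[self.field_cols[fid]]
            out[fid] = (D @ xl, A @ xl, B @ xl)
        return out

    def effect_vjp(self, r: np.ndarray, d: np.ndarray,
                   b: np.ndarray) -> np.ndarray:
        """Gradient of sum_i r_i e_i w.r.t. x, for e = a + b*d at given d, b.

        Uses de_i/dx_j = A_ij + B_ij d_i + D_ij b_i.
        """
        grad = np.zeros(self.n_spots)
        rd = r * d
        rb = r * b
        for fid, (D, A, B) in self.per_field.items():
            cols = self.field_cols[fid]
            grad[cols] = A.T @ r + B.T @ rd + D.T @ rb
        return grad

    def field_effect_vjp(self, fid: int, r: np.ndarray, d_l: np.ndarray,
                         b_l: np.ndarray) -> np.ndarray:
        """Same as :meth:`effect_vjp` but for one field's own effect."""
        D, A, B = self.per_field[fid]
        grad = np.zeros(self.n_spots)
        grad[self.field_cols[fid]] = A.T @ r + B.T @ (r * d_l) + D.T @ (r * b_l)
        return grad

    def rows_for_indices(self, linear_idx: np.ndarray) -> np.ndarray:
        """Row positions of the given linear grid indices (must be present)."""
        pos = np.searchsorted(self.voxel_idx, linear_idx)
        pos = np.clip(pos, 0, len(self.voxel_idx) - 1)
        ok = self.voxel_idx[pos] == linear_idx
        return pos[ok]


def default_calc_voxels(phantom: Phantom, dilation_mm: float = 10.0) -> np.ndarray:
    """Linear indices of BODY voxels within ``dilation_mm`` of any other ROI."""
    rois = [m for n, m in phantom.rois.items() if n != "BODY"]
    if not rois:
        return phantom.roi_indices("BODY")
    union = np.zeros(phantom.grid.dims, dtype=bool)
    for m in rois:
        union |= m
    if dilation_mm > 0:
        it = max(int(round(dilation_mm / min(phantom.grid.spacing))), 1)
        union = ndimage.binary_dilation(
            union, structure=ndimage.generate_binary_structure(3, 3), iterations=it
        )
    if "BODY" in phantom.rois:
        union &= phantom.rois["BODY"]
    return np.flatnonzero(union.ravel())


class DoseEngine:
    """Caches per-field geometry and evaluates influence for any scenario."""

    def __init__(
        self,
        phantom: Phantom,
        fields: Sequence[FieldGeometry],
        machine: MachineModel,
        voxel_idx: np.ndarray | None = None,
        calc_dilation_mm: float = 10.0,
        sparsity_rel_floor: float = 1e-4,
        kernel_cutoff_sigma: float = 3.5,
    ):
        self.phantom = phantom
        self.fields = list(fields)
        self.machine = machine
        self.cutoff = kernel_cutoff_sigma
        self.floor = sparsity_rel_floor
        if voxel_idx is None:
            voxel_idx = default_calc_voxels(phantom, calc_dilation_mm)
        self.voxel_idx = np.sort(np.asarray(voxel_idx))
        self.points = phantom.grid.voxel_centers()[self.voxel_idx]
        self.bev: list[BevWepl] = []
        self._u: list[np.ndarray] = []
        self._v: list[np.ndarray] = []
        self._w0: list[np.ndarray] = []
        for fg in self.fields:
            bev = BevWepl(phantom, fg)
            uh, vh, dh = fg.frame
            rel = self.points - np.asarray(fg.isocenter)
            u = rel @ uh
            v = rel @ vh
            z = rel @ dh
            self.bev.append(bev)
            self._u.append(u)
            self._v.append(v)
            self._w0.append(np.asarray(bev.sample(u, v, z), dtype=float))
        self._rtab: dict[float, tuple[np.ndarray, ...]] = {}

    # -- range-curve cache -------------------------------------------------

    def _range_tables(self, R: float):
        if R not in self._rtab:
            z, dose, let = self.machine.depth_curves(R)
            self._rtab[R] = (
                z,
                dose,
                self.machine.alpha_of_let(let),
                self.machine.beta_of_let(let),
            )
        return self._rtab[R]

    def _check_shift(self, scenario: Scenario) -> None:
        # beyond the BEV padding the shifted lateral lookups would clamp
        pad = min(b.pad_mm for b in self.bev) if self.bev else 0.0
        if np.linalg.norm(scenario.shift) > pad + 1e-9:
            raise ValueError(
                f"scenario shift {tuple(scenario.shift)} moves the target "
                "outside the modelled grid coverage "
                f"(max supported shift {pad:g} mm)"
            )

    # -- core kernel loop --------------------------------------------------

    def _spot_entries(self, rows_sel, fid, spots_f, scenario, floor):
        """Yield (local_rows, d, a, b) per spot of one field under a scenario."""
        uh, vh, dh = self.fields[fid].frame
        shift = np.asarray(scenario.shift, dtype=float)
        tu = float(shift @ uh)
        tv = float(shift @ vh)
        u = self._u[fid][rows_sel]
        v = self._v[fid][rows_sel]
        w = scenario.rho * self._w0[fid][rows_sel]
        sig = np.asarray(self.machine.sigma(w), dtype=float)
        order = np.argsort(u, kind="stable")
        u_s = u[order]
        for spot in spots_f:
            cut = self.cutoff * self.machine.sigma_max(spot.range_mm)
            cu = spot.u_mm - tu   # spot axis in intrinsic phantom coords
            cv = spot.v_mm - tv
            lo = np.searchsorted(u_s, cu - cut)
            hi = np.searchsorted(u_s, cu + cut)
            if hi <= lo:
                yield np.empty(0, dtype=np.int64), None, None, None
                continue
            cand = order[lo:hi]
            dv = v[cand] - cv
            m = np.abs(dv) <= cut
            cand = cand[m]
            if cand.size == 0:
                yield np.empty(0, dtype=np.int64), None, None, None
                continue
            dv = dv[m]
            du = u[cand] - cu
            s = sig[cand]
            r2 = du**2 + dv**2
            m2 = r2 <= (self.cutoff * s) ** 2
            cand, r2, s = cand[m2], r2[m2], s[m2]
            if cand.size == 0:
                yield np.empty(0, dtype=np.int64), None, None, None
                continue
            wz = w[cand]
            zt, dt, at, bt = self._range_tables(spot.range_mm)
            dz = np.interp(wz, zt, dt, left=0.0, right=0.0)
            kern = dz * np.exp(-r2 / (2.0 * s**2)) / (2.0 * np.pi * s**2)
            if floor > 0 and kern.size:
                keep = kern >= floor * kern.max()
                cand, kern, wz = cand[keep], kern[keep], wz[keep]
            if cand.size == 0:
                yield np.empty(0, dtype=np.int64), None, None, None
                continue
            av = np.interp(wz, zt, at)
            bv = np.interp(wz, zt, bt)
            yield cand, kern, av * kern, bv * kern

    def influence(
        self,
        spots: Sequence[Spot],
        scenario: Scenario | None = None,
        rows: np.ndarray | None = None,
        floor: float | None = None,
        dtype=np.float64,
    ) -> InfluenceSet:
        """Build the per-field sparse (D, A, B) matrices for one scenario."""
        scenario = scenario or nominal_scenario()
        self._check_shift(scenario)
        floor = self.floor if floor is None else floor
        rows_sel = np.arange(len(self.voxel_idx)) if rows is None else np.asarray(rows)
        nrows = len(rows_sel)
        spots = list(spots)
        per_field = {}
        field_cols = {}
        cols_by_field: dict[int, list[int]] = {}
        for j, s in enumerate(spots):
            cols_by_field.setdefault(s.field, []).append(j)
        for fid, cols in cols_by_field.items():
            spots_f = [spots[j] for j in cols]
            indptr = [0]
            indices: list[np.ndarray] = []
            dat_d: list[np.ndarray] = []
            dat_a: list[np.ndarray] = []
            dat_b: list[np.ndarray] = []
            for cand, kd, ka, kb in self._spot_entries(
                rows_sel, fid, spots_f, scenario, floor
            ):
                if cand.size:
                    o = np.argsort(cand, kind="stable")
                    indices.append(cand[o])
                    dat_d.append(kd[o].astype(dtype))
                    dat_a.append(ka[o].astype(dtype))
                    dat_b.append(kb[o].astype(dtype))
                indptr.append(indptr[-1] + cand.size)
            idx = (
                np.concatenate(indices)
                if indices
                else np.empty(0, dtype=np.int64)
            )
            shape = (nrows, len(cols))
            mk = lambda dat: sparse.csc_matrix(
                (
                    np.concatenate(dat) if dat else np.empty(0, dtype=dtype),
                    idx,
                    np.asarray(indptr),
                ),
                shape=shape,
            )
            per_field[fid] = (mk(dat_d), mk(dat_a), mk(dat_b))
            field_cols[fid] = np.asarray(cols)
        return InfluenceSet(
            scenario=scenario,
            grid=self.phantom.grid,
            voxel_idx=self.voxel_idx[rows_sel],
            spots=spots,
            per_field=per_field,
            field_cols=field_cols,
        )

    def scenario_dab(
        self,
        spots: Sequence[Spot],
        x: np.ndarray,
        scenario: Scenario | None = None,
        rows: np.ndarray | None = None,
        floor: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Accumulate (d, a, b) for fixed weights without building matrices."""
        scenario = scenario or nominal_scenario()
        self._check_shift(scenario)
        floor = self.floor if floor is None else floor
        rows_sel = np.arange(len(self.voxel_idx)) if rows is None else np.asarray(rows)
        x = np.asarray(x, dtype=float)
        d = np.zeros(len(rows_sel))
        a = np.zeros(len(rows_sel))
        b = np.zeros(len(rows_sel))
        spots = list(spots)
        cols_by_field: dict[int, list[int]] = {}
        for j, s in enumerate(spots):
            cols_by_field.setdefault(s.field, []).append(j)
        for fid, cols in cols_by_field.items():
            spots_f = [spots[j] for j in cols]
            xs = x[cols]
            for xj, (cand, kd, ka, kb) in zip(
                xs, self._spot_entries(rows_sel, fid, spots_f, scenario, floor)
            ):
                if cand.size and xj != 0.0:
                    d[cand] += xj * kd
                    a[cand] += xj * ka
                    b[cand] += xj * kb
        return d, a, b


def compute_influence(
    phantom: Phantom,
    spots: Sequence[Spot],
    fields: Sequence[FieldGeometry],
    machine: MachineModel,
    scenario: Scenario | None = None,
    **engine_kwargs,
) -> InfluenceSet:
    """One-shot convenience wrapper around :class:`DoseEngine`."""
    eng = DoseEngine(phantom, fields, machine, **engine_kwargs)
    return eng.influence(spots, scenario)


def save_influence(infl: InfluenceSet, path, key: str = "influence") -> None:
    """Cache an influence set in an HDF5 container under ``key``."""
    import h5py

    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.attrs["scenario_id"] = infl.scenario.id
        g.attrs["rho"] = infl.scenario.rho
        g.attrs["shift"] = infl.scenario.shift
        g.attrs["tag"] = infl.scenario.tag
        g.create_dataset("voxel_idx", data=infl.voxel_idx)
        if infl.grid is not None:
            g.attrs["grid_origin"] = infl.grid.origin
            g.attrs["grid_spacing"] = infl.grid.spacing
            g.attrs["grid_dims"] = infl.grid.dims
        g.create_dataset(
            "spots",
            data=np.array([(s.field, s.range_mm, s.u_mm, s.v_mm, s.weight_mu)
                           for s in infl.spots]),
        )
        for fid, mats in infl.per_field.items():
            fg = g.create_group(f"field_{fid}")
            fg.create_dataset("cols", data=infl.field_cols[fid])
            for name, M in zip(("D", "A", "B"), mats):
                mg = fg.create_group(name)
                mg.create_dataset("data", data=M.data)
                mg.create_dataset("indices", data=M.indices)
                mg.create_dataset("indptr", data=M.indptr)
                mg.attrs["shape"] = M.shape


def load_influence(path, key: str = "influence") -> InfluenceSet:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[key]
        scenario = Scenario(
            id=str(g.attrs["scenario_id"]), rho=float(g.attrs["rho"]),
            shift=tuple(g.attrs["shift"]), tag=str(g.attrs["tag"]),
        )
        grid = None
        if "grid_origin" in g.attrs:
            grid = VoxelGrid(
                tuple(g.attrs["grid_origin"]), tuple(g.attrs["grid_spacing"]),
                tuple(int(d) for d in g.attrs["grid_dims"]),
            )
        spots = [
            Spot(int(r[0]), float(r[1]), float(r[2]), float(r[3]), float(r[4]))
            for r in g["spots"][()]
        ]
        voxel_idx = g["voxel_idx"][()]
        per_field = {}
        field_cols = {}
        for name in g:
            if not name.startswith("field_"):
                continue
            fid = int(name.split("_")[1])
            fg = g[name]
            field_cols[fid] = fg["cols"][()]
            mats = []
            for mname in ("D", "A", "B"):
                mg = fg[mname]
                mats.append(sparse.csc_matrix(
                    (mg["data"][()], mg["indices"][()], mg["indptr"][()]),
                    shape=tuple(mg.attrs["shape"]),
                ))
            per_field[fid] = tuple(mats)
    return InfluenceSet(
        scenario=scenario, grid=grid, voxel_idx=voxel_idx,
        spots=spots, per_field=per_field, field_cols=field_cols,
    )


def physical_dose(infl: InfluenceSet, x: np.ndarray) -> DoseVolume:
    """Total physical dose volume d_i = sum_j d_ij x_j over all fields."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("spot weights must be nonnegative")
    if infl.grid is None:
        raise ValueError("influence set has no grid attached")
    d, _, _ = infl.dab(x)
    vol = np.zeros(int(np.prod(infl.grid.dims)))
    vol[infl.voxel_idx] = d
    return DoseVolume(grid=infl.grid, values=vol.reshape(infl.grid.dims))
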