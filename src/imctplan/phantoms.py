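"""Voxel phantoms, ROI masks and water-equivalent path-length ray tracing.

Two benchmark geometries are provided:

* an RTOG-style cylinder (232 mm diameter, 80 mm long) holding a C-shaped
  clinical target volume (CTV) wrapped around a cylindrical organ at risk
  (OAR), optionally with air/bone inserts adjacent to the target, and
* a cubic water phantom holding a donut-shaped target whose central hole
  acts as the OAR, with five cell-flask regions used for surviving-fraction
  prediction.

All coordinates are right-handed millimetres with the isocenter at the
phantom center; voxel indices are zero-based and refer to voxel centers.
Axis convention: x = left-right (LR), y = anteroposterior (AP),
z = superoinferior (SI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "Phantom",
    "Ray",
    "WeplResult",
    "RSP_WATER",
    "RSP_AIR",
    "RSP_BONE",
    "build_rtog_phantom",
    "build_donut_phantom",
    "build_water_box",
    "wepl_along_ray",
    "save_phantom",
    "load_phantom",
]

RSP_WATER = 1.0
RSP_AIR = 0.001
RSP_BONE = 1.53


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: ``origin`` is the center of voxel (0, 0, 0)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be strictly positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nvox, 3), C order."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for world points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) outer corners of the grid in mm."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.dims)
        return lo, hi


@dataclass
class Phantom:
    """Voxelized object: relative-stopping-power volume plus named ROI masks."""

    grid: VoxelGrid
    rsp: np.ndarray
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rsp = np.asarray(self.rsp, dtype=float)
        if self.rsp.shape != self.grid.dims:
            raise ValueError("rsp shape does not match grid dims")
        if np.any(self.rsp < 0):
            raise ValueError("rsp must be nonnegative")
        for name, mask in self.rois.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.grid.dims:
                raise ValueError(f"ROI {name!r} shape does not match grid dims")
            self.rois[name] = mask

    def roi_volume_mm3(self, name: str) -> float:
        return float(self.rois[name].sum()) * self.grid.voxel_volume

    def roi_indices(self, name: str) -> np.ndarray:
        """Linear (C-order) voxel indices of an ROI."""
        return np.flatnonzero(self.rois[name].ravel())


@dataclass(frozen=True)
class Ray:
    """Sampling ray: entry point, unit direction and sample step, all in mm."""

    entry: tuple[float, float, float]
    direction: tuple[float, float, float]
    step: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("ray direction must have unit norm")
        if self.step <= 0:
            raise ValueError("ray step must be positive")


class WeplResult(NamedTuple):
    wepl_mm: float
    hit: bool


def _sample_rsp(phantom: Phantom, points: np.ndarray) -> np.ndarray:
    """Trilinear RSP at world points; zero outside the grid outer extent.

    Inside the outer half-voxel shell the edge voxel's value is used, so a
    slab that extends to the grid face keeps its full water-equivalent
    thickness.
    """
    idx = phantom.grid.world_to_index(points).T
    vals = ndimage.map_coordinates(phantom.rsp, idx, order=1, mode="nearest")
    lo, hi = phantom.grid.extent()
    inside = np.all((points >= lo) & (points <= hi), axis=-1)
    return np.where(inside, vals, 0.0)


def wepl_along_ray(phantom: Phantom, ray: Ray, geometric_depth: float) -> WeplResult:
    """Water-equivalent path length: trapezoidal line integral of RSP.

    Integrates from the ray entry point to ``geometric_depth`` mm along the
    ray. A ray whose samples all fall outside the grid yields
    ``WeplResult(0.0, hit=False)``.
    """
    if geometric_depth < 0:
        raise ValueError("geometric depth must be nonnegative")
    if geometric_depth == 0:
        return WeplResult(0.0, True)
    n = max(int(np.ceil(geometric_depth / ray.step)), 1)
    t = np.linspace(0.0, geometric_depth, n + 1)
    pts = np.asarray(ray.entry) + t[:, None] * np.asarray(ray.direction)
    lo, hi = phantom.grid.extent()
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    if not inside.any():
        return WeplResult(0.0, False)
    rho = _sample_rsp(phantom, pts)
    wepl = float(np.trapezoid(rho, t))
    return WeplResult(wepl, True)


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------


def _grid_for_extent(extent_mm: np.ndarray, spacing: float) -> VoxelGrid:
    extent_mm = np.asarray(extent_mm, dtype=float)
    dims = tuple(int(np.ceil(e / spacing)) for e in extent_mm)
    origin = tuple(-(d - 1) * spacing / 2.0 for d in dims)
    return VoxelGrid(origin=origin, spacing=(spacing,) * 3, dims=dims)


def _cyl_mask(grid: VoxelGrid, radius: float, half_length: float,
              center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    p = grid.voxel_centers() - np.asarray(center)
    r2 = p[:, 0] ** 2 + p[:, 1] ** 2
    m = (r2 <= radius**2) & (np.abs(p[:, 2]) <= half_length)
    return m.reshape(grid.dims)


def build_rtog_phantom(
    heterogeneous: bool = False,
    spacing: float = 2.0,
    *,
    c_opening_deg: float = 90.0,
    c_opening_toward_deg: float = 0.0,
    oar_gap_mm: float = 0.0,
    insert_thickness_mm: float = 20.0,
    insert_offset_mm: float = 2.0,
) -> Phantom:
    """Cylindrical benchmark phantom with a C-shaped CTV around a rod OAR.

    Body: 232 mm diameter, 80 mm long, water (RSP 1.0); outside the body the
    grid is air. CTV: annulus of inner/outer diameter 18/40 mm, 40 mm long,
    with a ``c_opening_deg`` sector removed facing the
    ``c_opening_toward_deg`` port, minus the OAR (plus ``oar_gap_mm``) so the
    two masks are disjoint. OAR: cylinder of 30 mm diameter, 40 mm length.
    With ``heterogeneous`` an air slab (+x side) and a bone slab (-x side),
    each ``insert_thickness_mm`` thick, sit laterally adjacent to the CTV.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > 5:
        raise ValueError("spacing above 5 mm does not resolve the geometry")

    grid = _grid_for_extent(np.array([240.0, 240.0, 84.0]), spacing)
    body = _cyl_mask(grid, radius=116.0, half_length=40.0)
    rsp = np.where(body, RSP_WATER, RSP_AIR)

    oar = _cyl_mask(grid, radius=15.0, half_length=20.0)

    p = grid.voxel_centers()
    r = np.hypot(p[:, 0], p[:, 1])
    annulus = (r >= 9.0) & (r <= 20.0) & (np.abs(p[:, 2]) <= 20.0)
    # Opening sector faces the given port angle (port 0 looks down +y).
    port = np.deg2rad(c_opening_toward_deg)
    toward = np.array([np.sin(port), np.cos(port)])
    phi = np.arccos(
        np.clip((p[:, 0] * toward[0] + p[:, 1] * toward[1]) / np.maximum(r, 1e-9), -1, 1)
    )
    annulus &= phi > np.deg2rad(c_opening_deg / 2.0)
    ctv = annulus.reshape(grid.dims)
    keep_out = oar
    if oar_gap_mm > 0:
        it = max(int(round(oar_gap_mm / spacing)), 1)
        keep_out = ndimage.binary_dilation(oar, iterations=it)
    ctv &= ~keep_out

    rois = {"BODY": body, "CTV": ctv, "OAR": oar}

    if heterogeneous:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        x0 = 20.0 + insert_offset_mm
        air = (
            (x >= x0) & (x <= x0 + insert_thickness_mm)
            & (np.abs(y) <= 20.0) & (np.abs(z) <= 20.0)
        ).reshape(grid.dims) & body
        bone = (
            (x <= -x0) & (x >= -(x0 + insert_thickness_mm))
            & (np.abs(y) <= 20.0) & (np.abs(z) <= 20.0)
        ).reshape(grid.dims) & body
        rsp[air] = RSP_AIR
        rsp[bone] = RSP_BONE
        rois["AIR_INSERT"] = air
        rois["BONE_INSERT"] = bone

    return Phantom(grid=grid, rsp=rsp, rois=rois)


def build_donut_phantom(
    spacing: float = 2.5,
    *,
    cube_side_mm: float = 160.0,
    flask_radius_mm: float = 10.0,
    flask_half_height_mm: float = 5.0,
    flask_ring_radius_mm: float = 31.0,
    flask_angles_deg: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0),
) -> Phantom:
    """Cubic water phantom with a donut target and a central-hole OAR.

    Donut CTV: inner diameter 25 mm, outer diameter 100 mm, 100 mm long, axis
    along z. The hole (radius < 12.5 mm) is the OAR. Five cylindrical flask
    ROIs sit at the midplane: four inside the target on a ring, one centered
    in the OAR hole.
    """
    if spacing <= 0 or spacing > 5:
        raise ValueError("spacing must be in (0, 5] mm")
    grid = _grid_for_extent(np.array([cube_side_mm] * 3), spacing)
    rsp = np.full(grid.dims, RSP_WATER)

    p = grid.voxel_centers()
    r = np.hypot(p[:, 0], p[:, 1])
    inz = np.abs(p[:, 2]) <= 50.0
    ctv = ((r >= 12.5) & (r <= 50.0) & inz).reshape(grid.dims)
    oar = ((r < 12.5) & inz).reshape(grid.dims)
    body = np.ones(grid.dims, dtype=bool)
    rois = {"BODY": body, "CTV": ctv, "OAR": oar}

    centers = [
        (flask_ring_radius_mm * np.cos(np.deg2rad(a)),
         flask_ring_radius_mm * np.sin(np.deg2rad(a)), 0.0)
        for a in flask_angles_deg
    ] + [(0.0, 0.0, 0.0)]
    for k, c in enumerate(centers, start=1):
        d = p - np.asarray(c)
        m = (
            (np.hypot(d[:, 0], d[:, 1]) <= flask_radius_mm)
            & (np.abs(d[:, 2]) <= flask_half_height_mm)
        ).reshape(grid.dims)
        rois[f"FLASK{k}"] = m
    return Phantom(grid=grid, rsp=rsp, rois=rois)


def build_water_box(side_mm: float = 100.0, spacing: float = 2.0) -> Phantom:
    """Uniform water cube; handy for oracle tests of the dose engine."""
    grid = _grid_for_extent(np.array([side_mm] * 3), spacing)
    return Phantom(
        grid=grid,
        rsp=np.full(grid.dims, RSP_WATER),
        rois={"BODY": np.ones(grid.dims, dtype=bool)},
    )


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes + JSON sidecar
# ---------------------------------------------------------------------------


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def save_phantom(phantom: Phantom, prefix: str | Path) -> None:
    """Write ``<prefix>_rsp.nii.gz``, one mask volume per ROI and a sidecar."""
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.grid)
    nib.save(nib.Nifti1Image(phantom.rsp.astype(np.float32), aff),
             str(prefix) + "_rsp.nii.gz")
    for name, mask in phantom.rois.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                 str(prefix) + f"_roi_{name}.nii.gz")
    sidecar = {
        "origin": list(phantom.grid.origin),
        "spacing": list(phantom.grid.spacing),
        "dims": list(phantom.grid.dims),
        "rois": sorted(phantom.rois),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(prefix: str | Path) -> Phantom:
    import nibabel as nib

    meta = json.loads(Path(str(prefix) + ".json").read_text())
    grid = VoxelGrid(tuple(meta["origin"]), tuple(meta["spacing"]), tuple(meta["dims"]))
    rsp = np.asarray(nib.load(str(prefix) + "_rsp.nii.gz").dataobj, dtype=float)
    rois = {
        name: np.asarray(nib.load(str(prefix) + f"_roi_{name}.nii.gz").dataobj) > 0
        for name in meta["rois"]
    }
    return Phantom(grid=grid, rsp=rsp, rois=rois)
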