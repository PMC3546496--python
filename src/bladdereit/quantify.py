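"""Voxel-based volume and position quantification.

The tank is gridded at 1 mm (default 180 x 150 x 80 = 2,160,000 cubes of
1e-3 mL).  Grid nodes are classified as enclosed by the extracted
boundary surface; a cube counts toward the volume when at least four of
its eight vertices are enclosed and those vertices are not all on a
single cube face ("4 non-coplanar vertices").  Anomaly position is the
centre of mass of the half-amplitude (HA) set of the reconstruction,

    position = sum_m |dx_m| p_m / sum_m |dx_m|,

over elements with |dx_m| >= ha_fraction * max |dx|; position error is
the per-axis offset from the true anomaly centre as a percentage of the
tank extent on that axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .boundary import TriangleSurface
from .mesh import Mesh

logger = logging.getLogger(__name__)

#: node classified "on the surface" when a ray crossing is this close (mm)
_ON_TOL = 1e-9
#: column jitter (mm) used to dodge rays tangent to facets
_JITTER = 1e-6


@dataclass
class VoxelGrid:
    """Regular cube lattice for volume counting.

    ``dims`` counts cubes per axis; nodes number (nx+1)(ny+1)(nz+1).
    The default grid spans the 80 mm of tank depth below the agar cover
    (z from 5 to 85 mm).
    """

    spacing_mm: float = 1.0
    dims: tuple[int, int, int] = (180, 150, 80)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 5.0)
    inside_flags: np.ndarray | None = None  # (nx+1, ny+1, nz+1) bool

    def validate(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if min(self.dims) < 1:
            raise ValueError("grid dims must be positive")

    @property
    def n_cubes(self) -> int:
        return int(np.prod(self.dims))

    @property
    def n_nodes(self) -> int:
        return int(np.prod([d + 1 for d in self.dims]))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + self.spacing_mm * np.arange(
            self.dims[axis] + 1
        )

    @property
    def cube_volume_ml(self) -> float:
        return self.spacing_mm**3 / 1000.0


@dataclass
class AnomalyStats:
    """Volume and position figures of merit for one reconstruction."""

    valid_cube_count: int
    volume_ml: float
    position_mm: tuple[float, float, float] | None = None
    position_error_pct: tuple[float, float, float] | None = None
    volume_error_pct: float | None = None
    true_volume_ml: float | None = None
    true_position_mm: tuple[float, float, float] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def as_row(self) -> dict:
        return asdict(self)


# ----------------------------------------------------------------------
def classify_nodes(
    surface: TriangleSurface,
    grid: VoxelGrid,
    require_watertight: bool = True,
) -> VoxelGrid:
    """Flag grid nodes enclosed by (or on) the surface.

    Classification casts +z rays through every grid column and takes
    crossing parity, with deterministic sub-nanometre column jitter to
    avoid rays grazing facet edges; a node within tolerance of a
    crossing counts as enclosed.  Four diagonal jitter offsets are
    OR-combined so nodes lying exactly on axis-aligned facets are
    classified as enclosed from whichever side touches the interior.
    """
    grid.validate()
    if surface.is_empty:
        grid.inside_flags = np.zeros(
            tuple(d + 1 for d in grid.dims), dtype=bool
        )
        return grid
    if require_watertight and not surface.watertight:
        raise ValueError(
            "surface is not watertight; re-run the boundary growth/closure "
            "pass, or pass require_watertight=False to force classification"
        )
    xs, ys, zs = (grid.axis_coords(a) for a in range(3))
    flags = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    tri = surface.vertices[surface.triangles]  # (T, 3, 3)
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flags |= _classify_pass(
            tri, xs + sx * _JITTER, ys + sy * _JITTER, zs
        )
    grid.inside_flags = flags
    return grid


def _classify_pass(tri, xs, ys, zs) -> np.ndarray:
    """One scanline parity pass over the (jittered) grid columns."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # candidate columns per triangle from the projected bounding box
    txmin = tri[:, :, 0].min(axis=1)
    txmax = tri[:, :, 0].max(axis=1)
    tymin = tri[:, :, 1].min(axis=1)
    tymax = tri[:, :, 1].max(axis=1)
    ix0 = np.searchsorted(xs, txmin, side="left")
    ix1 = np.searchsorted(xs, txmax, side="right")
    iy0 = np.searchsorted(ys, tymin, side="left")
    iy1 = np.searchsorted(ys, tymax, side="right")
    cnt_x = np.maximum(ix1 - ix0, 0)
    cnt_y = np.maximum(iy1 - iy0, 0)
    counts = cnt_x * cnt_y
    keep = counts > 0
    if not keep.any():
        return np.zeros((nx, ny, nz), dtype=bool)
    t_idx = np.repeat(np.flatnonzero(keep), counts[keep])
    # expand (triangle, ix, iy) pairs
    within = np.concatenate([np.arange(c) for c in counts[keep]])
    ixs = ix0[t_idx] + within // cnt_y[t_idx]
    iys = iy0[t_idx] + within % cnt_y[t_idx]
    px, py = xs[ixs], ys[iys]

    a0, a1, a2 = v0[t_idx], v1[t_idx], v2[t_idx]
    d0 = (a1[:, 0] - a0[:, 0]) * (py - a0[:, 1]) - (a1[:, 1] - a0[:, 1]) * (
        px - a0[:, 0]
    )
    d1 = (a2[:, 0] - a1[:, 0]) * (py - a1[:, 1]) - (a2[:, 1] - a1[:, 1]) * (
        px - a1[:, 0]
    )
    d2 = (a0[:, 0] - a2[:, 0]) * (py - a2[:, 1]) - (a0[:, 1] - a2[:, 1]) * (
        px - a2[:, 0]
    )
    area2 = (a1[:, 0] - a0[:, 0]) * (a2[:, 1] - a0[:, 1]) - (
        a1[:, 1] - a0[:, 1]
    ) * (a2[:, 0] - a0[:, 0])
    nondeg = np.abs(area2) > 1e-14
    inside = (
        ((d0 >= 0) & (d1 >= 0) & (d2 >= 0))
        | ((d0 <= 0) & (d1 <= 0) & (d2 <= 0))
    ) & nondeg
    if not inside.any():
        return np.zeros((nx, ny, nz), dtype=bool)
    t_idx, ixs, iys = t_idx[inside], ixs[inside], iys[inside]
    px, py = px[inside], py[inside]
    # crossing height from the plane equation
    n = np.cross(v1[t_idx] - v0[t_idx], v2[t_idx] - v0[t_idx])
    base = v0[t_idx]
    zc = base[:, 2] - (
        n[:, 0] * (px - base[:, 0]) + n[:, 1] * (py - base[:, 1])
    ) / n[:, 2]

    col = ixs * ny + iys
    order = np.lexsort((zc, col))
    col, zc = col[order], zc[order]
    # merge duplicate crossings (ray through a shared facet edge)
    if len(col) > 1:
        dup = (col[1:] == col[:-1]) & (np.abs(zc[1:] - zc[:-1]) <= _ON_TOL)
        keep2 = np.concatenate([[True], ~dup])
        col, zc = col[keep2], zc[keep2]

    # parity: each crossing toggles all nodes strictly above it
    k0 = np.searchsorted(zs, zc + _ON_TOL, side="right")
    toggles = np.zeros((nx * ny, nz + 1), dtype=np.int64)
    np.add.at(toggles, (col, k0), 1)
    parity = (np.cumsum(toggles[:, :-1], axis=1) % 2).astype(bool)
    # "on the surface" nodes
    on = np.zeros((nx * ny, nz), dtype=bool)
    lo = np.searchsorted(zs, zc - _ON_TOL, side="left")
    hi = np.searchsorted(zs, zc + _ON_TOL, side="right")
    rng = np.flatnonzero(hi > lo)
    for i in rng:  # ranges are 0 or 1 nodes long in practice
        on[col[i], lo[i]:hi[i]] = True
    return (parity | on).reshape(nx, ny, nz)


def count_valid_cubes(grid: VoxelGrid, stats: AnomalyStats | None = None) -> AnomalyStats:
    """Count cubes with >= 4 enclosed, non-coplanar vertices."""
    if grid.inside_flags is None:
        raise ValueError("inside_flags not populated; run classify_nodes first")
    f = grid.inside_flags
    corners = np.stack(
        [
            f[dx : f.shape[0] - 1 + dx, dy : f.shape[1] - 1 + dy,
              dz : f.shape[2] - 1 + dz]
            for dx in (0, 1)
            for dy in (0, 1)
            for dz in (0, 1)
        ],
        axis=0,
    )  # (8, nx, ny, nz); corner order bit-coded (dx, dy, dz)
    cnt = corners.sum(axis=0)
    valid = cnt >= 5
    four = cnt == 4
    if four.any():
        # exclude the case where all four flagged vertices share a face
        faces = [
            [0, 1, 2, 3],  # dx = 0
            [4, 5, 6, 7],  # dx = 1
            [0, 1, 4, 5],  # dy = 0
            [2, 3, 6, 7],  # dy = 1
            [0, 2, 4, 6],  # dz = 0
            [1, 3, 5, 7],  # dz = 1
        ]
        coplanar = np.zeros_like(four)
        for idx in faces:
            coplanar |= corners[idx].all(axis=0) & four
        valid |= four & ~coplanar
    count = int(valid.sum())
    volume = count * grid.cube_volume_ml
    return AnomalyStats(valid_cube_count=count, volume_ml=volume)


def center_of_mass(
    delta_x: np.ndarray, mesh: Mesh, ha_fraction: float = 0.5
) -> np.ndarray:
    """|delta_x|-weighted centroid of the half-amplitude element set."""
    if not 0 < ha_fraction <= 1:
        raise ValueError("ha_fraction must lie in (0, 1]")
    mag = np.abs(np.asarray(delta_x, dtype=float))
    peak = mag.max()
    if peak <= 0:
        raise ValueError("all-zero perturbation has no centre of mass")
    sel = mag >= ha_fraction * peak
    w = mag[sel]
    p = mesh.tet_centroids[sel]
    return (w[:, None] * p).sum(axis=0) / w.sum()


def position_error(
    est_mm: np.ndarray, truth_mm: np.ndarray, tank
) -> np.ndarray:
    """Signed per-axis error as percent of the tank extent."""
    est = np.asarray(est_mm, dtype=float)
    tru = np.asarray(truth_mm, dtype=float)
    return (est - tru) / tank.extent_mm * 100.0


def volume_error(est_ml: float, truth_ml: float) -> float:
    """Signed relative volume error in percent."""
    if truth_ml <= 0:
        raise ValueError("true volume must be positive")
    return (est_ml - truth_ml) / truth_ml * 100.0
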