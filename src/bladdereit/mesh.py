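"""Tetrahedral meshing of the cuboid measurement tank.

The tank is discretized from a structured node lattice: each hexahedral
cell is split into six tetrahedra sharing the main diagonal (Kuhn
subdivision), which tiles the box exactly and is conforming for any
lattice spacing.  Gridlines may be snapped to electrode positions in the
plane and graded in z toward the electrode array, where current density
— and hence the need for resolution — is highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: boundary face tags
TAG_BOTTOM = 0
TAG_TOP = 1
TAG_SIDE = 2

# local faces of a tet, each opposite the omitted vertex
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])

# Kuhn subdivision of the unit cube: six tets around the 000-111 diagonal.
# Corner ids are bit-coded (bit0 = x, bit1 = y, bit2 = z).
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)


class MeshingError(RuntimeError):
    """Raised when the mesher produces a degenerate element."""


@dataclass
class Mesh:
    """Conforming tetrahedral mesh of the tank.

    Coordinates are millimetres with the origin at one bottom corner and
    z pointing toward the electrode array.  All indices are 0-based.
    """

    nodes: np.ndarray  # (n_nodes, 3) float, mm
    tets: np.ndarray  # (n_tets, 4) int
    boundary_faces: np.ndarray = field(default=None)  # (n_faces, 3) int
    boundary_tags: np.ndarray = field(default=None)  # (n_faces,) int

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.boundary_faces is None:
            self._extract_boundary()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @cached_property
    def tet_volumes(self) -> np.ndarray:
        """Signed volumes in mm^3 (positive for valid orientation)."""
        p = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        return v / 6.0

    @cached_property
    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @cached_property
    def grad_phi(self) -> np.ndarray:
        """P1 basis gradients, (n_tets, 4, 3), units 1/mm."""
        p = self.nodes[self.tets]  # (m,4,3)
        a = np.concatenate([np.ones((self.n_tets, 4, 1)), p], axis=2)
        inv = np.linalg.inv(a)  # columns of inv are basis coefficients
        return inv[:, 1:4, :].transpose(0, 2, 1)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique node-pair edges, (n_edges, 2), sorted pairs."""
        e = self.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        e = np.sort(e.reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def tet_edges(self) -> np.ndarray:
        """Per-tet global edge ids, (n_tets, 6)."""
        e = self.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        e = np.sort(e.reshape(-1, 2), axis=1)
        keys = e[:, 0] * self.n_nodes + e[:, 1]
        ref = self.edges[:, 0] * self.n_nodes + self.edges[:, 1]
        return np.searchsorted(ref, keys).reshape(self.n_tets, 6)

    @cached_property
    def mean_edge_length(self) -> float:
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    @cached_property
    def tet_neighbors(self) -> np.ndarray:
        """Face-adjacent tet per local face, (n_tets, 4); -1 on boundary."""
        faces = np.sort(self.tets[:, _TET_FACES].reshape(-1, 3), axis=1)
        order = np.lexsort(faces.T[::-1])
        sf = faces[order]
        owner = order // 4
        nbr = np.full(self.n_tets * 4, -1, dtype=np.int64)
        same = np.all(sf[1:] == sf[:-1], axis=1)
        i = np.flatnonzero(same)
        a, b = order[i], order[i + 1]
        nbr[a] = owner[i + 1]
        nbr[b] = owner[i]
        return nbr.reshape(self.n_tets, 4)

    @cached_property
    def node_volumes(self) -> np.ndarray:
        """Lumped nodal volumes (mm^3): a quarter of each incident tet."""
        w = np.zeros(self.n_nodes)
        np.add.at(w, self.tets.ravel(), np.repeat(self.tet_volumes / 4.0, 4))
        return w

    @cached_property
    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces)

    @cached_property
    def interior_node_mask(self) -> np.ndarray:
        m = np.ones(self.n_nodes, dtype=bool)
        m[self.boundary_nodes] = False
        return m

    @cached_property
    def stiffness_unit(self) -> sp.csr_matrix:
        """Galerkin stiffness matrix for unit conductivity (mm units)."""
        return assemble_stiffness(self, np.ones(self.n_tets))

    # ------------------------------------------------------------------
    def _extract_boundary(self) -> None:
        faces = np.sort(self.tets[:, _TET_FACES].reshape(-1, 3), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        bnd = uniq[counts == 1]
        c = self.nodes[bnd].mean(axis=1)
        zmin, zmax = self.nodes[:, 2].min(), self.nodes[:, 2].max()
        tol = 1e-9 * max(1.0, zmax - zmin)
        tags = np.full(len(bnd), TAG_SIDE, dtype=np.int64)
        tags[np.abs(c[:, 2] - zmin) < tol] = TAG_BOTTOM
        tags[np.abs(c[:, 2] - zmax) < tol] = TAG_TOP
        self.boundary_faces = bnd
        self.boundary_tags = tags

    def boundary_face_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_faces].mean(axis=1)

    def boundary_face_areas(self) -> np.ndarray:
        p = self.nodes[self.boundary_faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def surface_euler_characteristic(self) -> int:
        """V - E + F of the boundary surface (2 for a closed box)."""
        f = self.boundary_faces
        v = len(np.unique(f))
        e = np.unique(
            np.sort(f[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1), axis=0
        )
        return v - len(e) + len(f)

    # ------------------------------------------------------------------
    def write_vtk(self, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
        """Write legacy ASCII VTK unstructured grid with optional cell data."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nbladdereit mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {self.n_nodes} double\n")
            np.savetxt(fh, self.nodes, fmt="%.9g")
            fh.write(f"CELLS {self.n_tets} {self.n_tets * 5}\n")
            cells = np.column_stack(
                [np.full(self.n_tets, 4, dtype=np.int64), self.tets]
            )
            np.savetxt(fh, cells, fmt="%d")
            fh.write(f"CELL_TYPES {self.n_tets}\n")
            np.savetxt(fh, np.full(self.n_tets, 10, dtype=np.int64), fmt="%d")
            if cell_data:
                fh.write(f"CELL_DATA {self.n_tets}\n")
                for name, arr in cell_data.items():
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, np.asarray(arr, dtype=float), fmt="%.9g")

    def write_msh(self, path) -> None:
        """Write Gmsh MSH 2.2 ASCII."""
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
            fh.write(f"$Nodes\n{self.n_nodes}\n")
            for i, (x, y, z) in enumerate(self.nodes, start=1):
                fh.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
            fh.write("$EndNodes\n")
            fh.write(f"$Elements\n{self.n_tets}\n")
            for i, t in enumerate(self.tets + 1, start=1):
                fh.write(f"{i} 4 2 0 1 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            fh.write("$EndElements\n")


# ----------------------------------------------------------------------
def assemble_stiffness(mesh: Mesh, sigma: np.ndarray) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix sum_e sigma_e V_e grad_i . grad_j.

    With coordinates in mm and sigma per element, entries scale as
    sigma * mm; callers handle unit conversion.
    """
    g = mesh.grad_phi  # (m,4,3)
    ke = np.einsum("eik,ejk->eij", g, g) * (sigma * mesh.tet_volumes)[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    k = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return k.tocsr()


def _fill_segment(a: float, b: float, target: float) -> np.ndarray:
    """Uniform coordinates from a to b at roughly the target spacing."""
    if b - a < 1e-12:
        return np.array([a])
    n = max(1, int(round((b - a) / target)))
    return np.linspace(a, b, n + 1)


def _axis_coords(
    extent: float,
    target: float,
    snap_points: np.ndarray | None = None,
    fine_spacing: float | None = None,
) -> np.ndarray:
    """1D gridline coordinates, optionally refined through snap points.

    When snap points (electrode centres along the axis) are given, the
    span covering them is meshed uniformly at ``fine_spacing`` with
    gridlines passing exactly through every snap point, and the outer
    margins are filled at the coarse target spacing.
    """
    if snap_points is None or len(snap_points) == 0:
        return _fill_segment(0.0, extent, target)
    pts = np.sort(np.asarray(snap_points, dtype=float))
    h = fine_spacing if fine_spacing is not None else target
    lo, hi = pts[0] - h, pts[-1] + h
    lo = max(lo, 0.0)
    hi = min(hi, extent)
    n_mid = int(round((hi - lo) / h))
    mid = np.linspace(lo, hi, n_mid + 1)
    left = _fill_segment(0.0, lo, target)
    right = _fill_segment(hi, extent, target)
    coords = np.unique(np.concatenate([left, mid, right]))
    # drop near-duplicates from the joins
    keep = np.concatenate([[True], np.diff(coords) > 1e-9])
    return coords[keep]


def _graded_z(
    height: float, target: float, grading: float = 2.5, n_layers: int | None = None
) -> np.ndarray:
    """z gridlines graded from coarse (bottom) to fine (electrode plane)."""
    n = n_layers if n_layers is not None else max(3, int(round(height / target)))
    w = np.geomspace(grading, 1.0, n)
    w *= height / w.sum()
    z = np.concatenate([[0.0], np.cumsum(w)])
    z[-1] = height
    return z


def lattice_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> Mesh:
    """Kuhn tetrahedral mesh over the tensor-product lattice xs x ys x zs."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    if min(nx, ny, nz) < 1:
        raise MeshingError("lattice needs at least one cell per axis")
    xg, yg, zg = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([xg.ravel(), yg.ravel(), zg.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.empty((len(i), 8), dtype=np.int64)
    for b in range(8):
        bx, by, bz = b & 1, (b >> 1) & 1, (b >> 2) & 1
        corners[:, b] = nid(i + bx, j + by, k + bz)
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)

    mesh = Mesh(nodes=nodes, tets=tets)
    vol = mesh.tet_volumes
    neg = vol < 0
    if np.any(neg):
        tets[neg] = tets[neg][:, [0, 2, 1, 3]]
        mesh = Mesh(nodes=nodes, tets=tets)
        vol = mesh.tet_volumes
    bad = np.flatnonzero(vol <= 1e-12)
    if len(bad):
        raise MeshingError(
            f"degenerate tetrahedron (zero volume): element {bad[0]}"
        )
    return mesh


def build_tank_mesh(
    spec,
    layout=None,
    fine_spacing_mm: float | None = None,
    z_layers: int | None = None,
    z_grading: float = 2.5,
) -> Mesh:
    """Mesh the cuboid tank described by a :class:`~bladdereit.phantom.TankSpec`.

    When an electrode layout is supplied, in-plane gridlines are snapped
    to the electrode centres (at ``fine_spacing_mm``, default half the
    array pitch so electrode face patches of adjacent electrodes never
    overlap) and the vertical spacing is graded toward the electrode
    plane.
    """
    spec.validate()
    sx = sy = None
    fine = None
    if layout is not None:
        c = np.asarray(layout.centers, dtype=float)
        sx = np.unique(np.round(c[:, 0], 9))
        sy = np.unique(np.round(c[:, 1], 9))
        fine = fine_spacing_mm if fine_spacing_mm is not None else layout.pitch_mm / 2.0
        ratio = layout.pitch_mm / fine
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "in-plane fine spacing must divide the electrode pitch so "
                "gridlines pass through every electrode centre"
            )
    xs = _axis_coords(spec.length_mm, spec.target_edge_mm, sx, fine)
    ys = _axis_coords(spec.width_mm, spec.target_edge_mm, sy, fine)
    zs = _graded_z(spec.height_mm, spec.target_edge_mm, z_grading, z_layers)
    mesh = lattice_mesh(xs, ys, zs)
    logger.info(
        "tank mesh: %d nodes, %d tets (target edge %.1f mm)",
        mesh.n_nodes,
        mesh.n_tets,
        spec.target_edge_mm,
    )
    return mesh
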