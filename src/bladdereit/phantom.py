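"""Synthetic cuboid phantom: tank, planar electrode array, inclusions, noise.

The default phantom reproduces the physical measurement setup the
package targets: an 18 x 15 x 10 cm tank, an 8 x 8 array of 4 mm
electrodes at 8 mm gaps on the top surface, a back (ground) electrode on
the bottom centre, saline-like inclusions of 0.892 S/m embedded in a
0.1 S/m background, and 10 mA current injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import Mesh, TAG_BOTTOM, TAG_TOP, build_tank_mesh

BACKGROUND_S_PER_M = 0.1
INCLUSION_S_PER_M = 0.892
CURRENT_MA = 10.0
N_ARRAY_ELECTRODES = 64
#: thickness of the agar layer covering the inclusion, below the array
COVER_MM = 15.0


@dataclass
class TankSpec:
    """Cuboid tank dimensions and mesh density control (mm)."""

    length_mm: float = 180.0
    width_mm: float = 150.0
    height_mm: float = 100.0
    target_edge_mm: float = 10.0

    def validate(self) -> None:
        dims = (self.length_mm, self.width_mm, self.height_mm)
        if min(dims) <= 0 or self.target_edge_mm <= 0:
            raise ValueError("tank dimensions and target edge must be positive")
        if self.target_edge_mm >= min(dims) / 4:
            raise ValueError("target_edge_mm must be < min dimension / 4")

    @property
    def volume_mm3(self) -> float:
        return self.length_mm * self.width_mm * self.height_mm

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array([self.length_mm, self.width_mm, self.height_mm])

    @property
    def center_mm(self) -> np.ndarray:
        return self.extent_mm / 2.0


@dataclass
class ElectrodeLayout:
    """8 x 8 top-surface electrode array plus one back (ground) electrode.

    ``centers`` lists the 64 array electrodes in row-major order (rows
    along y, columns along x).  The back electrode is the signal ground:
    index 64, never a measurement electrode.
    """

    centers: np.ndarray  # (64, 3) mm, on the top surface
    radius_mm: float = 2.0
    gap_mm: float = 8.0
    back_center: np.ndarray = None  # (3,) mm, on the bottom surface
    back_radius_mm: float = 15.0
    contact_impedance_ohm_m2: float = 0.01

    @property
    def pitch_mm(self) -> float:
        return 2 * self.radius_mm + self.gap_mm

    @property
    def n_electrodes(self) -> int:
        """Total electrode count including the back electrode."""
        return len(self.centers) + 1

    @classmethod
    def grid(
        cls,
        tank: TankSpec,
        n_rows: int = 8,
        n_cols: int = 8,
        radius_mm: float = 2.0,
        gap_mm: float = 8.0,
        back_radius_mm: float = 15.0,
        contact_impedance_ohm_m2: float = 0.01,
    ) -> "ElectrodeLayout":
        """Centred rectangular array on the top face, back electrode below."""
        pitch = 2 * radius_mm + gap_mm
        cx, cy = tank.length_mm / 2, tank.width_mm / 2
        xs = cx + (np.arange(n_cols) - (n_cols - 1) / 2) * pitch
        ys = cy + (np.arange(n_rows) - (n_rows - 1) / 2) * pitch
        centers = np.array(
            [[x, y, tank.height_mm] for y in ys for x in xs]
        )
        layout = cls(
            centers=centers,
            radius_mm=radius_mm,
            gap_mm=gap_mm,
            back_center=np.array([cx, cy, 0.0]),
            back_radius_mm=back_radius_mm,
            contact_impedance_ohm_m2=contact_impedance_ohm_m2,
        )
        layout.validate(tank)
        return layout

    def validate(self, tank: TankSpec) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.shape != (N_ARRAY_ELECTRODES, 3):
            raise ValueError("layout requires exactly 64 array electrodes")
        if self.back_center is None:
            raise ValueError("layout requires exactly one back electrode")
        r = self.radius_mm
        if (
            (c[:, 0] - r < 0).any()
            or (c[:, 0] + r > tank.length_mm).any()
            or (c[:, 1] - r < 0).any()
            or (c[:, 1] + r > tank.width_mm).any()
        ):
            raise ValueError("electrode footprint escapes the tank top face")
        d = np.linalg.norm(c[None, :, :2] - c[:, None, :2], axis=2)
        np.fill_diagonal(d, np.inf)
        if (d < 2 * r).any():
            raise ValueError("electrode footprints overlap")
        bc = np.asarray(self.back_center, dtype=float)
        if (
            bc[0] - self.back_radius_mm < 0
            or bc[0] + self.back_radius_mm > tank.length_mm
            or bc[1] - self.back_radius_mm < 0
            or bc[1] + self.back_radius_mm > tank.width_mm
        ):
            raise ValueError("back electrode escapes the tank bottom face")

    def face_sets(self, mesh: Mesh) -> list[np.ndarray]:
        """Boundary-face patch for each of the 65 electrodes.

        An electrode owns every top-surface face whose centroid falls
        inside its disc, plus the faces incident to the top node nearest
        its centre — the fallback guarantees at least three faces per
        electrode on any lattice mesh without local remeshing.
        """
        cents = mesh.boundary_face_centroids()
        top = np.flatnonzero(mesh.boundary_tags == TAG_TOP)
        bottom = np.flatnonzero(mesh.boundary_tags == TAG_BOTTOM)
        sets: list[np.ndarray] = []
        for center, radius, cand in [
            *[(c, self.radius_mm, top) for c in self.centers],
            (self.back_center, self.back_radius_mm, bottom),
        ]:
            center = np.asarray(center, dtype=float)
            d = np.linalg.norm(cents[cand][:, :2] - center[None, :2], axis=1)
            patch = set(cand[d <= radius].tolist())
            # nearest-node fallback
            cand_nodes = np.unique(mesh.boundary_faces[cand])
            nn = cand_nodes[
                np.argmin(
                    np.linalg.norm(
                        mesh.nodes[cand_nodes, :2] - center[None, :2], axis=1
                    )
                )
            ]
            incident = cand[np.any(mesh.boundary_faces[cand] == nn, axis=1)]
            patch.update(incident.tolist())
            sets.append(np.array(sorted(patch), dtype=np.int64))
        flat = np.concatenate(sets[:N_ARRAY_ELECTRODES])
        if len(np.unique(flat)) != len(flat):
            raise ValueError(
                "electrode face patches overlap; refine the mesh in-plane"
            )
        for i, s in enumerate(sets):
            if len(s) < 3:
                raise ValueError(f"electrode {i} resolved by < 3 faces")
        return sets

    def contact_impedances(self) -> np.ndarray:
        return np.full(self.n_electrodes, self.contact_impedance_ohm_m2)


@dataclass
class InclusionSpec:
    """A conductive anomaly (cuboid or sphere) inside the tank."""

    shape: str  # "cuboid" | "sphere"
    center_mm: np.ndarray
    dims_mm: np.ndarray | float  # edge lengths (cuboid) or radius (sphere)
    conductivity_s_per_m: float = INCLUSION_S_PER_M

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.shape not in ("cuboid", "sphere"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if self.shape == "cuboid":
            self.dims_mm = np.asarray(self.dims_mm, dtype=float)

    @property
    def volume_mm3(self) -> float:
        if self.shape == "cuboid":
            return float(np.prod(self.dims_mm))
        return 4.0 / 3.0 * np.pi * float(self.dims_mm) ** 3

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - self.center_mm
        if self.shape == "cuboid":
            return np.all(np.abs(p) <= np.asarray(self.dims_mm) / 2.0, axis=1)
        return np.linalg.norm(p, axis=1) <= float(self.dims_mm)

    def check_inside(self, tank: TankSpec) -> None:
        if self.shape == "cuboid":
            lo = self.center_mm - np.asarray(self.dims_mm) / 2.0
            hi = self.center_mm + np.asarray(self.dims_mm) / 2.0
        else:
            lo = self.center_mm - float(self.dims_mm)
            hi = self.center_mm + float(self.dims_mm)
        if (lo < 0).any() or (hi > tank.extent_mm).any():
            raise ValueError("inclusion escapes the tank interior")

    def to_surface(self, subdivisions: int = 4) -> trimesh.Trimesh:
        """Analytic ground-truth boundary surface of the inclusion."""
        if self.shape == "cuboid":
            box = trimesh.creation.box(extents=np.asarray(self.dims_mm))
            box.apply_translation(self.center_mm)
            return box
        sphere = trimesh.creation.icosphere(
            subdivisions=subdivisions, radius=float(self.dims_mm)
        )
        sphere.apply_translation(self.center_mm)
        return sphere


@dataclass
class ConductivityField:
    """Per-element conductivity in S/m on a given mesh."""

    values: np.ndarray
    mesh: Mesh

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_tets:
            raise ValueError("conductivity length != number of tetrahedra")

    def validate_reference(self) -> None:
        if (self.values <= 0).any():
            raise ValueError("reference conductivity must be positive everywhere")


def make_conductivity_field(
    mesh: Mesh,
    background: float = BACKGROUND_S_PER_M,
    inclusions: list[InclusionSpec] | None = None,
    tank: TankSpec | None = None,
) -> ConductivityField:
    """Piecewise-constant field: inclusion value where the element centroid
    falls inside an inclusion, background elsewhere."""
    if background <= 0:
        raise ValueError("background conductivity must be positive")
    values = np.full(mesh.n_tets, background, dtype=float)
    cents = mesh.tet_centroids
    for inc in inclusions or []:
        if tank is not None:
            inc.check_inside(tank)
        values[inc.contains(cents)] = inc.conductivity_s_per_m
    return ConductivityField(values=values, mesh=mesh)


def add_noise(frame, snr_db: float | None, seed: int):
    """Additive zero-mean Gaussian noise at a prescribed frame SNR.

    SNR is defined against the RMS of the frame values:
    ``sigma_noise = rms / 10^(snr_db / 20)``.  ``snr_db`` of None or
    +inf returns the frame unchanged.
    """
    from .forward import MeasurementFrame

    if snr_db is None or np.isinf(snr_db):
        return frame
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    rng = np.random.default_rng(seed)
    rms = float(np.sqrt(np.mean(frame.values**2)))
    sigma = rms / 10.0 ** (snr_db / 20.0)
    noisy = frame.values + rng.normal(0.0, sigma, size=frame.values.shape)
    return MeasurementFrame(
        values=noisy, current_ma=frame.current_ma, frame_kind="measured"
    )


# ----------------------------------------------------------------------
#: named inclusion models matching the bladder-filling experiment series
INCLUSION_MODELS = {
    "empty": None,
    "cube40": (np.array([40.0, 40.0, 40.0]), 64.0),
    "cube50": (np.array([50.0, 50.0, 50.0]), 125.0),
    "slab80": (np.array([80.0, 80.0, 50.0]), 320.0),
}


def standard_inclusion(name: str, tank: TankSpec | None = None) -> InclusionSpec | None:
    """One of the standard saline models, centred in-plane with its top
    face one agar-cover thickness (15 mm) below the electrode plane."""
    tank = tank or TankSpec()
    if name not in INCLUSION_MODELS:
        raise KeyError(f"unknown inclusion model {name!r}")
    entry = INCLUSION_MODELS[name]
    if entry is None:
        return None
    dims, _ = entry
    top_z = tank.height_mm - COVER_MM
    center = np.array(
        [tank.length_mm / 2.0, tank.width_mm / 2.0, top_z - dims[2] / 2.0]
    )
    return InclusionSpec(shape="cuboid", center_mm=center, dims_mm=dims)


def desk_phantom(
    target_edge_mm: float = 10.0,
) -> tuple[TankSpec, ElectrodeLayout, Mesh]:
    """Default desk-scale phantom: tank, layout and mesh (~30k tets)."""
    tank = TankSpec(target_edge_mm=target_edge_mm)
    layout = ElectrodeLayout.grid(tank)
    return tank, layout, build_tank_mesh(tank, layout)


#: mesh presets: (target_edge_mm, in-plane fine spacing, z layers, grading)
MESH_PRESETS = {
    "coarse": (24.0, 6.0, 4, 2.0),  # ~9k tets: quick tests, diagnostics
    "desk": (10.0, 6.0, None, 2.5),  # ~32k tets: interactive default
    "paper": (13.0, 4.0, 16, 2.2),  # ~75k tets / ~14k nodes: study fidelity
}


def phantom_preset(name: str = "desk") -> tuple[TankSpec, ElectrodeLayout, Mesh]:
    """Tank, electrode layout and mesh at a named discretization preset.

    ``paper`` reproduces the scale of the reference experiment's mesh
    (~79k elements, ~15k nodes); ``desk`` is the everyday default;
    ``coarse`` is for fast tests.
    """
    if name not in MESH_PRESETS:
        raise KeyError(f"unknown mesh preset {name!r}")
    target, fine, z_layers, grading = MESH_PRESETS[name]
    tank = TankSpec(target_edge_mm=target)
    layout = ElectrodeLayout.grid(tank)
    mesh = build_tank_mesh(
        tank, layout, fine_spacing_mm=fine, z_layers=z_layers, z_grading=grading
    )
    return tank, layout, mesh
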