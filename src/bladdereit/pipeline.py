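"""End-to-end orchestration: simulate -> reconstruct -> extract -> quantify.

A single YAML config describes the phantom, the regularized solver, the
edge-detection stage and the quantification grid; every stage persists
its artifacts (CSV frames, VTK mesh fields, STL/PLY surfaces, JSON
stats) so runs can be resumed and inspected.  All randomness flows from
the one config seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import boundary as bd
from . import forward as fw
from . import inverse as inv
from . import quantify as qt
from .mesh import build_tank_mesh
from .phantom import (
    BACKGROUND_S_PER_M,
    MESH_PRESETS,
    ConductivityField,
    ElectrodeLayout,
    InclusionSpec,
    TankSpec,
    add_noise,
    make_conductivity_field,
    standard_inclusion,
)

logger = logging.getLogger(__name__)


class TankConfig(BaseModel):
    length_mm: float = 180.0
    width_mm: float = 150.0
    height_mm: float = 100.0
    target_edge_mm: float = 10.0


class ElectrodesConfig(BaseModel):
    radius_mm: float = 2.0
    gap_mm: float = 8.0
    back_radius_mm: float = 15.0
    contact_impedance_ohm_m2: float = 0.01


class InclusionConfig(BaseModel):
    model: Optional[str] = None  # named standard model, e.g. "cube40"
    shape: Literal["cuboid", "sphere"] = "cuboid"
    center_mm: Optional[list[float]] = None
    dims_mm: Optional[list[float] | float] = None
    conductivity_s_per_m: float = 0.892


class PhantomConfig(BaseModel):
    preset: Optional[str] = "desk"  # mesh preset; None = use tank.target_edge_mm
    tank: TankConfig = Field(default_factory=TankConfig)
    electrodes: ElectrodesConfig = Field(default_factory=ElectrodesConfig)
    inclusions: list[InclusionConfig] = Field(default_factory=list)
    background_s_per_m: float = BACKGROUND_S_PER_M
    current_ma: float = 10.0
    noise_snr_db: Optional[float] = 40.0  # None = noiseless
    seed: int = 0


class InverseConfig(BaseModel):
    method: Literal["tikhonov", "noser", "combined"] = "combined"
    lam: Optional[float] = None  # None = 1e-3 * trace(J'J)/n
    epsilon: float = 0.05


class BoundaryConfig(BaseModel):
    threshold_t: float | Literal["auto"] = "auto"
    auto_percentile: float = 90.0
    min_component_size: int = 10
    growth_min_edges: int = 2
    use_magnitude: bool = True
    core_min_amplitude: float = 0.25


class QuantifyConfig(BaseModel):
    spacing_mm: float = 1.0
    dims: tuple[int, int, int] = (180, 150, 80)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 5.0)
    ha_fraction: float = 0.5


class PipelineConfig(BaseModel):
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    inverse: InverseConfig = Field(default_factory=InverseConfig)
    boundary: BoundaryConfig = Field(default_factory=BoundaryConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


# ----------------------------------------------------------------------
def _build_phantom(cfg: PhantomConfig):
    tank = TankSpec(**cfg.tank.model_dump())
    layout = ElectrodeLayout.grid(
        tank,
        radius_mm=cfg.electrodes.radius_mm,
        gap_mm=cfg.electrodes.gap_mm,
        back_radius_mm=cfg.electrodes.back_radius_mm,
        contact_impedance_ohm_m2=cfg.electrodes.contact_impedance_ohm_m2,
    )
    if cfg.preset is not None:
        target, fine, z_layers, grading = MESH_PRESETS[cfg.preset]
        tank.target_edge_mm = target
        mesh = build_tank_mesh(
            tank, layout, fine_spacing_mm=fine, z_layers=z_layers, z_grading=grading
        )
    else:
        mesh = build_tank_mesh(tank, layout)
    return tank, layout, mesh


def _inclusions(cfg: PhantomConfig, tank: TankSpec) -> list[InclusionSpec]:
    out = []
    for ic in cfg.inclusions:
        if ic.model is not None:
            inc = standard_inclusion(ic.model, tank)
            if inc is not None:
                out.append(inc)
            continue
        out.append(
            InclusionSpec(
                shape=ic.shape,
                center_mm=np.asarray(ic.center_mm, dtype=float),
                dims_mm=(
                    np.asarray(ic.dims_mm, dtype=float)
                    if ic.shape == "cuboid"
                    else float(ic.dims_mm)
                ),
                conductivity_s_per_m=ic.conductivity_s_per_m,
            )
        )
    return out


class PipelineRun:
    """In-memory pipeline state with per-stage artifact persistence."""

    def __init__(self, config: PipelineConfig, outdir=None):
        self.config = config
        self.outdir = Path(outdir if outdir is not None else config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        self.tank, self.layout, self.mesh = _build_phantom(config.phantom)
        self.inclusions = _inclusions(config.phantom, self.tank)
        logger.info(
            "phantom: %d nodes / %d tets, %d inclusion(s) [%.1fs]",
            self.mesh.n_nodes,
            self.mesh.n_tets,
            len(self.inclusions),
            time.perf_counter() - t0,
        )
        self._system_ref = None
        self.frame_ref: fw.MeasurementFrame | None = None
        self.frame_meas: fw.MeasurementFrame | None = None
        self.jacobian: fw.SensitivityMatrix | None = None
        self.result: inv.ReconstructionResult | None = None
        self.field: bd.NodeScalarField | None = None
        self.edge_set: bd.EdgeElementSet | None = None
        self.surface: bd.TriangleSurface | None = None
        self.stats: qt.AnomalyStats | None = None

    # -- stage 1 -------------------------------------------------------
    def simulate(self) -> None:
        """Reference (clean, simulated) and measured (noisy) frames.

        The reference frame is the forward computation F(x_p) on the
        homogeneous model; only the inclusion frame plays the role of a
        physical measurement and carries the configured noise.
        """
        cfg = self.config.phantom
        t0 = time.perf_counter()
        field_ref = make_conductivity_field(
            self.mesh, cfg.background_s_per_m
        )
        self._system_ref = fw.CEMSystem(
            self.mesh,
            field_ref.values,
            self.layout.face_sets(self.mesh),
            self.layout.contact_impedances(),
        )
        self.frame_ref = fw.simulate_frame(
            self.mesh, field_ref, self.layout, cfg.current_ma, system=self._system_ref
        )
        field_inc = make_conductivity_field(
            self.mesh, cfg.background_s_per_m, self.inclusions, self.tank
        )
        frame_inc = fw.simulate_frame(self.mesh, field_inc, self.layout, cfg.current_ma)
        self.frame_meas = add_noise(frame_inc, cfg.noise_snr_db, cfg.seed)
        logger.info("simulate: two 4032-value frames [%.1fs]", time.perf_counter() - t0)

        self.frame_ref.to_csv(self.outdir / "frame_reference.csv")
        self.frame_meas.to_csv(self.outdir / "frame_measured.csv")
        self.mesh.write_vtk(
            self.outdir / "phantom.vtk",
            cell_data={"sigma_true_s_per_m": field_inc.values},
        )
        for i, inc in enumerate(self.inclusions):
            inc.to_surface().export(self.outdir / f"truth_inclusion_{i}.stl")
        self._log_run()

    def load_frames(self, ref_path, meas_path) -> None:
        self.frame_ref = fw.MeasurementFrame.from_csv(ref_path)
        self.frame_meas = fw.MeasurementFrame.from_csv(meas_path)

    # -- stage 2 -------------------------------------------------------
    def reconstruct(self) -> inv.ReconstructionResult:
        if self.frame_ref is None:
            self.load_frames(
                self.outdir / "frame_reference.csv",
                self.outdir / "frame_measured.csv",
            )
        cfg = self.config.inverse
        t0 = time.perf_counter()
        if self.jacobian is None:
            field_ref = make_conductivity_field(
                self.mesh, self.config.phantom.background_s_per_m
            )
            self.jacobian = fw.compute_jacobian(
                self.mesh,
                field_ref,
                self.layout,
                self.config.phantom.current_ma,
                system=self._system_ref,
            )
        dv = self.frame_ref.values - self.frame_meas.values
        self.result = inv.solve(self.jacobian, dv, inv.RegularizationConfig(**cfg.model_dump()))
        logger.info(
            "reconstruct (%s): residual %.3g [%.1fs]",
            cfg.method,
            self.result.residual_norm,
            time.perf_counter() - t0,
        )
        self.mesh.write_vtk(
            self.outdir / "reconstruction.vtk",
            cell_data={"delta_x_s_per_m": self.result.delta_x},
        )
        with open(self.outdir / "reconstruction.json", "w") as fh:
            json.dump(
                {
                    "method": self.result.method,
                    "params": self.result.params,
                    "residual_norm": self.result.residual_norm,
                },
                fh,
                indent=2,
            )
        return self.result

    # -- stage 3 -------------------------------------------------------
    def extract(self) -> bd.TriangleSurface:
        if self.result is None:
            raise RuntimeError("run reconstruct before extract")
        cfg = self.config.boundary
        t0 = time.perf_counter()
        self.edge_set, self.surface, self.field = boundary_stage(
            self.mesh, self.result.delta_x, cfg
        )
        logger.info(
            "extract: %d edge elements, %d triangles, watertight=%s [%.1fs]",
            len(self.edge_set),
            self.surface.n_triangles,
            self.surface.watertight,
            time.perf_counter() - t0,
        )
        self.mesh.write_vtk(
            self.outdir / "edge_elements.vtk",
            cell_data={"edge_element": self.edge_set.to_cell_array()},
        )
        if not self.surface.is_empty:
            self.surface.save(self.outdir / "surface.stl")
            self.surface.save(self.outdir / "surface.ply")
        return self.surface

    # -- stage 4 -------------------------------------------------------
    def quantify(self) -> qt.AnomalyStats:
        if self.surface is None:
            raise RuntimeError("run extract before quantify")
        cfg = self.config.quantify
        t0 = time.perf_counter()
        truth = self.inclusions[0] if len(self.inclusions) == 1 else None
        stats = quantify_stage(
            self.surface,
            self.result.delta_x if self.result is not None else np.zeros(1),
            self.mesh,
            self.tank,
            cfg,
            truth=truth,
        )
        self.stats = stats
        logger.info(
            "quantify: %d valid cubes -> %.1f mL [%.1fs]",
            stats.valid_cube_count,
            stats.volume_ml,
            time.perf_counter() - t0,
        )
        stats.to_json(self.outdir / "stats.json")
        self._append_results_csv(stats)
        return stats

    # ------------------------------------------------------------------
    def _append_results_csv(self, stats: qt.AnomalyStats) -> None:
        import pandas as pd

        path = self.outdir / "results.csv"
        row = pd.json_normalize(stats.as_row())
        row.insert(0, "seed", self.config.phantom.seed)
        header = not path.exists()
        row.to_csv(path, mode="a", header=header, index=False)

    def _log_run(self) -> None:
        with open(self.outdir / "run.json", "w") as fh:
            json.dump(
                {
                    "config": self.config.model_dump(),
                    "n_nodes": self.mesh.n_nodes,
                    "n_tets": self.mesh.n_tets,
                },
                fh,
                indent=2,
                default=str,
            )


def boundary_stage(
    mesh, delta_x: np.ndarray, cfg: BoundaryConfig
) -> tuple[bd.EdgeElementSet, bd.TriangleSurface, bd.NodeScalarField]:
    """Detection, filtering and closed-shell extraction for one image."""
    img = np.abs(delta_x) if cfg.use_magnitude else -np.asarray(delta_x)
    field = bd.differentiate(bd.element_to_node_field(mesh, img))
    det_cfg = bd.EdgeDetectionConfig(
        threshold_t=cfg.threshold_t,
        auto_percentile=cfg.auto_percentile,
        min_component_size=cfg.min_component_size,
        growth_min_edges=cfg.growth_min_edges,
        use_magnitude=cfg.use_magnitude,
    )
    t_thr = bd.select_threshold(field, det_cfg)
    edge_set = bd.filter_and_grow(
        bd.detect_edge_elements(mesh, field, t_thr), mesh, det_cfg
    )
    surface = bd.extract_closed_surface(
        edge_set, field, mesh, cfg.core_min_amplitude
    )
    return edge_set, surface, field


def quantify_stage(
    surface: bd.TriangleSurface,
    delta_x: np.ndarray,
    mesh,
    tank: TankSpec,
    cfg: QuantifyConfig,
    truth: InclusionSpec | None = None,
) -> qt.AnomalyStats:
    """Voxel counting plus figures of merit against an optional truth."""
    grid = qt.VoxelGrid(
        spacing_mm=cfg.spacing_mm, dims=cfg.dims, origin_mm=cfg.origin_mm
    )
    qt.classify_nodes(surface, grid, require_watertight=False)
    stats = qt.count_valid_cubes(grid)
    if np.any(np.asarray(delta_x) != 0):
        pos = qt.center_of_mass(delta_x, mesh, cfg.ha_fraction)
        stats.position_mm = tuple(pos)
        if truth is not None:
            stats.true_volume_ml = truth.volume_ml
            stats.true_position_mm = tuple(truth.center_mm)
            stats.position_error_pct = tuple(
                qt.position_error(pos, truth.center_mm, tank)
            )
            stats.volume_error_pct = qt.volume_error(
                stats.volume_ml, truth.volume_ml
            )
    return stats


def _model_seed(seed: int, index: int) -> int:
    """Per-model noise seed derived from the study seed (below 2^31)."""
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0]
        % 2**31
    )


def run_study(
    models: tuple[str, ...] = ("cube40", "cube50", "slab80"),
    preset: str = "paper",
    noise_snr_db: float | None = 40.0,
    seed: int = 1,
    inverse_config: InverseConfig | None = None,
    boundary_config: BoundaryConfig | None = None,
    quantify_config: QuantifyConfig | None = None,
) -> list[qt.AnomalyStats]:
    """Run the full pipeline for several inclusion models on one phantom.

    The homogeneous reference frame, Jacobian and solver factorization
    are shared across models; each model simulates its own "measured"
    frame, adds seeded noise, reconstructs and quantifies.  This is the
    simulated analogue of the physical bladder-filling series.
    """
    from .phantom import phantom_preset

    inverse_config = inverse_config or InverseConfig()
    boundary_config = boundary_config or BoundaryConfig()
    quantify_config = quantify_config or QuantifyConfig()
    tank, layout, mesh = phantom_preset(preset)
    field_ref = make_conductivity_field(mesh)
    system = fw.CEMSystem(
        mesh, field_ref.values, layout.face_sets(mesh), layout.contact_impedances()
    )
    frame_ref = fw.simulate_frame(mesh, field_ref, layout, system=system)
    jac = fw.compute_jacobian(mesh, field_ref, layout, system=system)
    solver = inv.RidgeReconstructor(
        jac,
        method=inverse_config.method,
        lam=inverse_config.lam,
        epsilon=inverse_config.epsilon,
    )
    out = []
    for k, name in enumerate(models):
        inc = standard_inclusion(name, tank)
        field_inc = make_conductivity_field(
            mesh, inclusions=[inc] if inc else [], tank=tank
        )
        frame_meas = add_noise(
            fw.simulate_frame(mesh, field_inc, layout),
            noise_snr_db,
            _model_seed(seed, k),
        )
        result = solver.solve(frame_ref.values - frame_meas.values)
        _, surface, _ = boundary_stage(mesh, result.delta_x, boundary_config)
        stats = quantify_stage(
            surface, result.delta_x, mesh, tank, quantify_config, truth=inc
        )
        logger.info(
            "study %s: volume %.1f mL (true %s), PE %s",
            name,
            stats.volume_ml,
            stats.true_volume_ml,
            stats.position_error_pct,
        )
        out.append(stats)
    return out


def run_simulate(config: PipelineConfig, outdir=None) -> PipelineRun:
    """Forward-simulate the phantom and persist both measurement frames."""
    run = PipelineRun(config, outdir)
    run.simulate()
    return run


def run_full(
    config: PipelineConfig, outdir=None, frames: tuple | None = None
) -> qt.AnomalyStats:
    """Execute the whole pipeline; optionally start from persisted frames.

    ``frames`` may name (reference_csv, measured_csv) to skip forward
    simulation of the measured data (the reference model is still
    needed for the Jacobian).
    """
    run = PipelineRun(config, outdir)
    if frames is not None:
        run.load_frames(*frames)
    else:
        run.simulate()
    run.reconstruct()
    run.extract()
    return run.quantify()
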