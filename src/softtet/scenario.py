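"""Configuration-driven scenarios: YAML schema, scene assembly, runners.

A scenario file describes a mesh source (file or phantom), a material
(preset name or explicit E in kPa + Poisson's ratio), solver settings,
colliders, constraint toggles and output options.  Unknown keys are
rejected.  Given the same config and seed, a scenario run is a pure
function of its inputs: frames and metrics are byte-stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .collision import Box, Plane, SDFShape, Sphere
from .constraints import ConstraintSet, build_constraints
from .material import Material, preset_by_name
from .metrics import MetricsObserver
from .solver import SimState, SolverConfig, run
from .tet_mesh import TetMesh, load_mesh, make_box_phantom, make_ellipsoid_phantom, save_mesh

__all__ = ["ScenarioConfig", "build_scene", "run_scenario", "compare_modes", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSpec(_Strict):
    shape: Literal["box", "ellipsoid"]
    cells: tuple[int, int, int] = (2, 2, 2)
    extent: tuple[float, float, float] = (0.1, 0.1, 0.1)
    semi_axes: tuple[float, float, float] = (0.08, 0.05, 0.06)
    resolution: int = 8


class MeshSpec(_Strict):
    path: Optional[str] = None
    format: Literal["auto", "tetgen", "vtk"] = "auto"
    phantom: Optional[PhantomSpec] = None
    pinned: list[int] = Field(default_factory=list)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.path is None) == (self.phantom is None):
            raise ValueError("mesh: exactly one of 'path' or 'phantom' is required")
        return self


class OverrideSpec(_Strict):
    distance: Optional[float] = None
    volume: Optional[float] = None
    neo_hydro: Optional[float] = None
    neo_dev: Optional[float] = None
    shape_stiffness: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class MaterialSpec(_Strict):
    preset: Optional[str] = None
    young_modulus_kpa: Optional[float] = Field(default=None, gt=0)
    poisson_ratio: Optional[float] = Field(default=None, ge=0, lt=0.5)
    density: float = Field(default=1000.0, gt=0)
    overrides: OverrideSpec = Field(default_factory=OverrideSpec)

    @model_validator(mode="after")
    def _preset_or_explicit(self):
        explicit = self.young_modulus_kpa is not None and self.poisson_ratio is not None
        if (self.preset is None) == (not explicit):
            pass  # either preset alone or explicit pair alone is fine; both is an error
        if self.preset is not None and explicit:
            raise ValueError("material: give a preset or explicit values, not both")
        if self.preset is None and not explicit:
            raise ValueError("material: need a preset or young_modulus_kpa + poisson_ratio")
        return self


class ShapeMatchSpec(_Strict):
    enabled: bool = False
    clusters: Literal["global", "grid"] = "global"
    cluster_cells: int = Field(default=2, ge=1)
    stiffness: Optional[float] = Field(default=None, ge=0, le=1)


class ConstraintToggles(_Strict):
    distance: bool = True
    volume: bool = True
    neo: bool = True
    shape_matching: ShapeMatchSpec = Field(default_factory=ShapeMatchSpec)
    rest_correction: bool = False


class ColliderSpec(_Strict):
    type: Literal["plane", "sphere", "box"]
    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 1.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 1.0
    half_extents: tuple[float, float, float] = (1.0, 1.0, 1.0)
    friction: float = Field(default=0.0, ge=0)
    restitution: float = Field(default=0.0, ge=0, le=1)

    def build(self) -> SDFShape:
        if self.type == "plane":
            return Plane(point=np.array(self.point), normal=np.array(self.normal),
                         friction_coeff=self.friction, restitution=self.restitution)
        if self.type == "sphere":
            return Sphere(center=np.array(self.center), radius=self.radius,
                          friction_coeff=self.friction, restitution=self.restitution)
        return Box(center=np.array(self.center), half_extents=np.array(self.half_extents),
                   friction_coeff=self.friction, restitution=self.restitution)


class SolverSpec(_Strict):
    dt: float = Field(default=1.0 / 60.0, gt=0)
    substeps: int = Field(default=64, ge=1)
    iterations: int = Field(default=1, ge=1)
    gravity: tuple[float, float, float] = (0.0, -9.81, 0.0)
    velocity_damping: float = Field(default=0.0, ge=0)
    mode: Literal["xpbd", "pbd"] = "xpbd"
    # None = compliance-matched per family from the material (see
    # solver.matched_pbd_stiffness); a dict gives explicit k values.
    pbd_stiffness: Optional[dict[str, float]] = None
    contact_thickness: float = Field(default=1e-3, ge=0)
    ccd: bool = False


class InitialSpec(_Strict):
    drop_height: float = Field(default=0.0, ge=0)  # lift above y=0 before the run
    jitter: float = Field(default=0.0, ge=0)  # seeded random initial velocity (m/s)


class OutputSpec(_Strict):
    directory: Optional[str] = None
    frame_format: Literal["obj", "vtk", "none"] = "none"
    metric_cadence: int = Field(default=1, ge=1)


class ScenarioConfig(_Strict):
    mesh: MeshSpec
    material: MaterialSpec
    solver: SolverSpec = Field(default_factory=SolverSpec)
    constraints: ConstraintToggles = Field(default_factory=ConstraintToggles)
    colliders: list[ColliderSpec] = Field(default_factory=list)
    initial: InitialSpec = Field(default_factory=InitialSpec)
    output: OutputSpec = Field(default_factory=OutputSpec)
    frames: int = Field(default=60, ge=0)
    seed: int = 0


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    return ScenarioConfig.model_validate(data)


def _build_material(spec: MaterialSpec) -> Material:
    if spec.preset is not None:
        mat = preset_by_name(spec.preset, density=spec.density)
        mat.compliance_overrides = spec.overrides.as_dict()
        return mat
    return Material.from_young_poisson(
        spec.young_modulus_kpa * 1000.0,
        spec.poisson_ratio,
        density=spec.density,
        overrides=spec.overrides.as_dict(),
    )


def build_scene(config: ScenarioConfig):
    """Assemble (mesh, material, constraints, colliders, solver config, state)."""
    mspec = config.mesh
    material = _build_material(config.material)
    if mspec.phantom is not None:
        ph = mspec.phantom
        if ph.shape == "box":
            mesh = make_box_phantom(*ph.cells, extent=ph.extent, density=material.density)
        else:
            mesh = make_ellipsoid_phantom(
                ph.semi_axes, ph.resolution, density=material.density
            )
    else:
        mesh = load_mesh(mspec.path, mspec.format, density=material.density)
    if mspec.pinned:
        mesh.pin(mspec.pinned)

    sm = config.constraints.shape_matching
    constraints = build_constraints(
        mesh,
        material,
        distance=config.constraints.distance,
        volume=config.constraints.volume,
        neo=config.constraints.neo,
        shape_matching=sm.enabled,
        shape_clusters=sm.clusters,
        cluster_cells=sm.cluster_cells,
        shape_stiffness=sm.stiffness,
        rest_correction=config.constraints.rest_correction,
    )
    colliders = [c.build() for c in config.colliders]
    if config.solver.pbd_stiffness is None:
        from .solver import matched_pbd_stiffness

        h = config.solver.dt / config.solver.substeps
        pbd_ks = matched_pbd_stiffness(mesh, constraints, h)
    else:
        pbd_ks = dict(config.solver.pbd_stiffness)
    solver_config = SolverConfig(
        dt=config.solver.dt,
        substeps=config.solver.substeps,
        iterations=config.solver.iterations,
        gravity=np.asarray(config.solver.gravity),
        velocity_damping=config.solver.velocity_damping,
        mode=config.solver.mode,
        pbd_stiffness=pbd_ks,
        contact_thickness=config.solver.contact_thickness,
        ccd=config.solver.ccd,
        seed=config.seed,
    )

    state = SimState.from_mesh(mesh)
    if config.initial.drop_height > 0:
        lift = config.initial.drop_height - state.positions[:, 1].min()
        state.positions[:, 1] += lift
        mesh.rest_positions[:, 1] += lift  # rest pose follows the rigid lift
        state.prev_positions[:] = state.positions
        # shape-match rest offsets are translation-invariant; nothing else moves
    if config.initial.jitter > 0:
        rng = np.random.default_rng(config.seed)
        state.velocities += config.initial.jitter * rng.standard_normal(
            state.velocities.shape
        )
        state.velocities[mesh.inv_mass == 0] = 0.0
    return mesh, material, constraints, colliders, solver_config, state


def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None):
    """Run a scenario, writing frames, metrics.csv and the resolved config.

    Returns the MetricsObserver (its ``records`` hold one row per frame).
    """
    mesh, material, constraints, colliders, solver_config, state = build_scene(config)
    out = Path(out_dir) if out_dir else (
        Path(config.output.directory) if config.output.directory else None
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
        )

    observer = MetricsObserver(
        mesh, constraints, colliders, solver_config.contact_thickness
    )

    def frame_writer(frame: int, st) -> None:
        if out is None or config.output.frame_format == "none":
            return
        if frame % config.output.metric_cadence:
            return
        ext = "obj" if config.output.frame_format == "obj" else "vtk"
        fmt = "obj_surface" if ext == "obj" else "vtk"
        save_mesh(mesh, st.positions, out / f"frame_{frame:05d}.{ext}", fmt)

    try:
        run(state, mesh, constraints, colliders, solver_config, config.frames,
            observers=(observer, frame_writer))
    finally:
        # on solver divergence keep the frames and metrics produced so far
        if out is not None and observer.records:
            observer.to_dataframe().to_csv(out / "metrics.csv", index=False)
    return observer


def max_deformation_summary(observer: MetricsObserver) -> dict:
    """Summary at the maximum-deformation frame (the frame minimizing S)."""
    df = observer.to_dataframe()
    i = int(df["smoothness_mean"].idxmin())
    row = df.loc[i]
    return {
        "max_deformation_frame": int(row["frame"]),
        "smoothness_mean": float(row["smoothness_mean"]),
        "smoothness_std": float(row["smoothness_std"]),
        "volume_drift_min": float(df["volume_drift"].min()),
        "volume_drift_max": float(df["volume_drift"].max()),
        "max_penetration": float(df["max_penetration"].max()),
        "final_kinetic_energy": float(df["kinetic_energy"].iloc[-1]),
    }


def compare_modes(
    config: ScenarioConfig, modes: tuple[str, ...] = ("xpbd", "pbd"), out_dir=None
):
    """Run the identical scenario once per solver mode; summarize each.

    Returns {mode: summary dict}; writes a combined comparison.csv when an
    output directory is given.
    """
    import pandas as pd

    results = {}
    for mode in modes:
        cfg = config.model_copy(deep=True)
        cfg.solver.mode = mode
        observer = run_scenario(cfg, out_dir=None)
        summary = max_deformation_summary(observer)
        summary["mode"] = mode
        summary["substeps"] = cfg.solver.substeps
        results[mode] = summary
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(list(results.values())).to_csv(out / "comparison.csv", index=False)
    return results
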