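"""Substepped XPBD time integration (with a legacy-PBD comparison mode).

Each frame of duration ``dt`` is split into ``substeps`` equal substeps of
duration h.  Per substep: reset Lagrange multipliers, predict positions with
semi-implicit Euler under external acceleration, run ``iterations``
Gauss-Seidel sweeps over the constraint families in a fixed deterministic
order (tet-elastic hydrostatic+deviatoric per element, volume, distance,
then shape matching as a positional pass, then contacts), update velocities
from the position change, and apply the contact velocity response
(restitution).  Compliances are rescaled per substep (alpha_tilde = alpha/h^2)
so the material stiffness, not the stepping scheme, sets the behaviour.

In ``pbd`` mode the same constraints are projected with iteration-compensated
stiffness factors k' = 1 - (1 - k)^(1/iterations) and no multiplier state:
the classic formulation whose effective stiffness depends on iteration count
and timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .collision import Contact, SDFShape
from .constraints import ConstraintSet, shape_match_corrections
from .tet_mesh import TetMesh

__all__ = [
    "SimState",
    "SolverConfig",
    "SolverDivergenceError",
    "predict",
    "project",
    "update_velocities",
    "step",
    "run",
]


class SolverDivergenceError(RuntimeError):
    """Raised when a position turns non-finite during projection."""


@dataclass
class SimState:
    positions: np.ndarray
    prev_positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    step_count: int = 0

    @classmethod
    def from_mesh(cls, mesh: TetMesh) -> "SimState":
        x = mesh.rest_positions.copy()
        return cls(
            positions=x,
            prev_positions=x.copy(),
            velocities=np.zeros_like(x),
        )

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.prev_positions.copy(),
            self.velocities.copy(),
            self.time,
            self.step_count,
        )


def _default_pbd_stiffness() -> dict:
    return {"distance": 1.0, "volume": 1.0, "neo_hydro": 1.0, "neo_dev": 1.0}


@dataclass
class SolverConfig:
    dt: float = 1.0 / 60.0  # frame step (s)
    substeps: int = 64
    iterations: int = 1  # projection sweeps per substep
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    velocity_damping: float = 0.0  # per-second rate
    mode: str = "xpbd"  # or "pbd"
    pbd_stiffness: dict = field(default_factory=_default_pbd_stiffness)
    contact_thickness: float = 1e-3
    ccd: bool = False
    seed: int = 0

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, float)
        if self.substeps < 1 or self.iterations < 1:
            raise ValueError("substeps and iterations must be >= 1")
        if self.mode not in ("xpbd", "pbd"):
            raise ValueError(f"unknown solver mode {self.mode!r}")
        ks = _default_pbd_stiffness()
        ks.update(self.pbd_stiffness)
        unknown = set(ks) - set(_default_pbd_stiffness())
        if unknown:
            raise ValueError(f"unknown pbd_stiffness keys: {sorted(unknown)}")
        for name, k in ks.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"pbd_stiffness[{name!r}]={k} outside [0, 1]")
        self.pbd_stiffness = ks


def _compensated(k: float, iterations: int) -> float:
    """Iteration-compensated PBD stiffness k' = 1 - (1 - k)^(1/iterations)."""
    return 1.0 - (1.0 - k) ** (1.0 / iterations)


def matched_pbd_stiffness(mesh: TetMesh, constraints: ConstraintSet, h: float) -> dict:
    """Per-family PBD stiffness matched to the constraint compliances.

    Legacy PBD can only express one dimensionless stiffness k per constraint
    family.  The per-visit correction of a compliant constraint equals a PBD
    correction with k = D/(D + alpha/h^2), where D = sum_k w_k |grad_k C|^2
    at the rest pose.  This returns the median of that equivalence over each
    family, i.e. the best single k a stiffness-tuned baseline could use at
    substep duration h — which is precisely what it cannot do per element.
    """
    w = mesh.inv_mass
    h2 = h * h
    out = dict(_default_pbd_stiffness())
    if len(constraints.d_rest):
        D = w[constraints.d_ids[:, 0]] + w[constraints.d_ids[:, 1]]
        out["distance"] = float(np.median(D / (D + constraints.d_alpha / h2)))
    if len(constraints.v_rest):
        p = mesh.rest_positions[constraints.v_ids]
        e1, e2, e3 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        g2 = np.cross(e2, e3) / 6.0
        g3 = np.cross(e3, e1) / 6.0
        g4 = np.cross(e1, e2) / 6.0
        g1 = -(g2 + g3 + g4)
        D = sum(
            w[constraints.v_ids[:, k]] * (g * g).sum(axis=1)
            for k, g in enumerate((g1, g2, g3, g4))
        )
        out["volume"] = float(np.median(D / (D + constraints.v_alpha / h2)))
    if len(constraints.t_rest_vol):
        # At rest F = I: dC_H/dF = I and dC_D/dF = I/sqrt(3); per-vertex
        # gradients are the columns of inv_rest_shape^T (scaled).
        B = constraints.t_inv_rest
        g234 = np.swapaxes(B, 1, 2)  # (m, 3 vertices, 3) gradient rows
        g1 = -g234.sum(axis=1, keepdims=True)
        grads = np.concatenate([g1, g234], axis=1)  # (m, 4, 3)
        wt = w[constraints.t_ids]  # (m, 4)
        D = (wt * (grads**2).sum(axis=2)).sum(axis=1)
        out["neo_hydro"] = float(np.median(D / (D + constraints.t_alpha_h / h2)))
        D3 = D / 3.0
        out["neo_dev"] = float(np.median(D3 / (D3 + constraints.t_alpha_d / h2)))
    return out


def predict(state: SimState, h: float, external_accel: np.ndarray, inv_mass: np.ndarray) -> None:
    """Semi-implicit Euler prediction: v += h a; prev <- x; x += h v (free vertices)."""
    if h <= 0:
        raise ValueError("substep duration must be positive")
    free = (inv_mass > 0)[:, None]
    state.velocities += np.where(free, h * external_accel, 0.0)
    state.prev_positions[:] = state.positions
    state.positions += np.where(free, h * state.velocities, 0.0)


def _check_finite(positions: np.ndarray, family: str) -> None:
    if not np.isfinite(positions).all():
        bad = int(np.flatnonzero(~np.isfinite(positions).all(axis=1))[0])
        raise SolverDivergenceError(
            f"non-finite position at vertex {bad} after {family} projection"
        )


def project(
    positions: np.ndarray,
    inv_mass: np.ndarray,
    constraints: ConstraintSet,
    config: SolverConfig,
    h: float,
) -> None:
    """Run the configured Gauss-Seidel sweeps over all constraint families."""
    h2 = h * h
    mode = _kernels.MODE_XPBD if config.mode == "xpbd" else _kernels.MODE_PBD
    ks = config.pbd_stiffness
    it = config.iterations
    for _ in range(it):
        if len(constraints.t_rest_vol):
            _kernels.project_neo_pass(
                positions, inv_mass,
                constraints.t_ids, constraints.t_inv_rest, constraints.t_offset,
                constraints.t_alpha_h / h2, constraints.t_alpha_d / h2,
                constraints.t_lambda_h, constraints.t_lambda_d,
                mode, _compensated(ks["neo_hydro"], it), _compensated(ks["neo_dev"], it),
            )
            _check_finite(positions, "tet-elastic")
        if len(constraints.v_rest):
            _kernels.project_volume_pass(
                positions, inv_mass,
                constraints.v_ids, constraints.v_rest,
                constraints.v_alpha / h2, constraints.v_lambda,
                mode, _compensated(ks["volume"], it),
            )
            _check_finite(positions, "volume")
        if len(constraints.d_rest):
            _kernels.project_distance_pass(
                positions, inv_mass,
                constraints.d_ids, constraints.d_rest,
                constraints.d_alpha / h2, constraints.d_lambda,
                mode, _compensated(ks["distance"], it),
            )
            _check_finite(positions, "distance")
        for cluster in constraints.clusters:
            # Cluster stiffness is a per-frame fraction; compensate it across
            # the substeps*iterations visits of one frame so the rigidifying
            # pull is independent of the stepping scheme.
            eff = _compensated(cluster.stiffness, config.substeps * it)
            dx = shape_match_corrections(cluster, positions)
            if cluster.stiffness > 0:
                dx *= eff / cluster.stiffness
            movable = inv_mass[cluster.member_ids] > 0
            positions[cluster.member_ids[movable]] += dx[movable]
        if constraints.clusters:
            _check_finite(positions, "shape-matching")


def update_velocities(state: SimState, h: float, damping: float) -> None:
    """v = (x - x_prev)/h, scaled by max(0, 1 - damping*h)."""
    state.velocities[:] = (state.positions - state.prev_positions) / h
    state.velocities *= max(0.0, 1.0 - damping * h)


def _contact_stage(
    state: SimState,
    inv_mass: np.ndarray,
    colliders: list[SDFShape],
    config: SolverConfig,
    v_pre: np.ndarray,
):
    """Project contacts (hard), apply positional friction; return velocity-response info."""
    pos = state.positions
    responses = []  # (vertex, normal, restitution, pre normal speed)
    for shape in colliders:
        d, n = shape.query_batch(pos)
        mask = (d < config.contact_thickness) & (inv_mass > 0)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        depth = config.contact_thickness - d[idx]
        nrm = n[idx]
        pos[idx] += nrm * depth[:, None]
        mu = shape.friction_coeff
        if mu > 0:
            disp = pos[idx] - state.prev_positions[idx]
            dn = np.einsum("ij,ij->i", disp, nrm)
            disp_t = disp - dn[:, None] * nrm
            slide = np.linalg.norm(disp_t, axis=1)
            limit = mu * depth
            scale = np.where(slide <= limit, 1.0, np.divide(
                limit, np.maximum(slide, 1e-300)))
            pos[idx] -= disp_t * scale[:, None]
        vn_pre = np.einsum("ij,ij->i", v_pre[idx], nrm)
        for k, v in enumerate(idx):
            responses.append((int(v), nrm[k], shape.restitution, float(vn_pre[k])))
    return responses


def _ccd_stage(state: SimState, colliders: list[SDFShape], config: SolverConfig) -> None:
    from .collision import ccd_toi

    for shape in colliders:
        d_prev = shape.query_batch(state.prev_positions)[0]
        d_now = shape.query_batch(state.positions)[0]
        seg = np.linalg.norm(state.positions - state.prev_positions, axis=1)
        # A segment can only reach the surface if it is at least as long as
        # the start distance (SDF is 1-Lipschitz); this bound also catches
        # full tunnelling where both endpoints are outside.
        maybe = np.flatnonzero(
            (d_prev >= config.contact_thickness)
            & ((d_now < config.contact_thickness)
               | (seg >= d_prev - config.contact_thickness))
        )
        for v in maybe:
            t = ccd_toi(state.prev_positions[v], state.positions[v], shape,
                        thickness=config.contact_thickness)
            if t is not None and t < 1.0:
                hit = state.prev_positions[v] + t * (
                    state.positions[v] - state.prev_positions[v])
                state.positions[v] = hit


def step(
    state: SimState,
    mesh: TetMesh,
    constraints: ConstraintSet,
    colliders: list[SDFShape],
    config: SolverConfig,
    applied_forces: np.ndarray | None = None,
) -> SimState:
    """Advance the state by one frame of dt (in-place; returns the state)."""
    h = config.dt / config.substeps
    accel = np.broadcast_to(config.gravity, state.positions.shape).copy()
    if applied_forces is not None:
        accel = accel + mesh.inv_mass[:, None] * np.asarray(applied_forces, float)
    for _ in range(config.substeps):
        constraints.reset_lambdas()
        predict(state, h, accel, mesh.inv_mass)
        v_pre = state.velocities.copy()
        if config.ccd and colliders:
            _ccd_stage(state, colliders, config)
        project(state.positions, mesh.inv_mass, constraints, config, h)
        responses = _contact_stage(state, mesh.inv_mass, colliders, config, v_pre)
        update_velocities(state, h, config.velocity_damping)
        for v, n, restitution, vn_pre in responses:
            if vn_pre < 0:
                vn = state.velocities[v] @ n
                state.velocities[v] += n * (-restitution * vn_pre - vn)
    state.time += config.dt
    state.step_count += 1
    return state


def run(
    state: SimState,
    mesh: TetMesh,
    constraints: ConstraintSet,
    colliders: list[SDFShape],
    config: SolverConfig,
    n_frames: int,
    observers: tuple = (),
    applied_forces: np.ndarray | None = None,
):
    """Advance n_frames, invoking each observer after every frame.

    Returns (state, records) where records[i] is the list of the observers'
    return values for frame i.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    records = []
    for frame in range(n_frames):
        step(state, mesh, constraints, colliders, config, applied_forces)
        records.append([obs(frame, state) for obs in observers])
    return state, records
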