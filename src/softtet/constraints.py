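"""Compliant-constraint evaluation and the XPBD update rules.

Four constraint families act on the particle system:

* distance:      C = |x_i - x_j| - d                  (edge springs)
* volume:        C = (1/6)(x21 x x31) . x41 - V       (per-tet volume)
* Neo-Hookean:   C_H = det(F) - 1,  C_D = ||F||_F     (per-tet hyperelastic)
* shape matching: blended positional pull toward the best-fit rigid pose of
  a particle cluster (polar decomposition), outside the multiplier machinery.

Each compliant constraint carries a compliance alpha (inverse stiffness) and
an accumulated Lagrange multiplier lambda_acc, updated per Gauss-Seidel visit

    dlambda = (-C - alpha_tilde * lambda_acc)
              / (sum_k w_k |grad_k C|^2 + alpha_tilde)

with alpha_tilde = alpha / h^2 for substep duration h, followed by the
position update x_k += w_k * grad_k C * dlambda.

The record-level functions here are the plain-numpy reference implementation;
the solver runs numerically identical vectorized kernels (see
:mod:`softtet._kernels`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .material import Material, element_compliances
from .tet_mesh import TetMesh

log = logging.getLogger(__name__)

__all__ = [
    "DistanceConstraint",
    "VolumeConstraint",
    "TetElasticConstraint",
    "ShapeMatchCluster",
    "ConstraintSet",
    "eval_distance",
    "eval_volume",
    "deformation_gradient",
    "eval_neo_hydrostatic",
    "eval_neo_deviatoric",
    "best_fit_transform",
    "shape_match_corrections",
    "xpbd_delta_lambda",
    "apply_position_update",
    "build_constraints",
]

DEGENERATE_TOL = 1e-12


@dataclass
class DistanceConstraint:
    i: int
    j: int
    rest_length: float
    alpha: float = 0.0
    lambda_acc: float = 0.0


@dataclass
class VolumeConstraint:
    ids: np.ndarray  # 4 vertex indices
    rest_volume: float
    alpha: float = 0.0
    lambda_acc: float = 0.0


@dataclass
class TetElasticConstraint:
    """Per-tet stable Neo-Hookean constraint pair (hydrostatic + deviatoric).

    ``rest_offset`` shifts the hydrostatic target: C_H = det(F) - 1 - offset.
    The plain formulation uses offset 0; the rest-corrected variant uses
    offset mu/lambda, which zeroes the net elastic force at the rest pose.
    """

    ids: np.ndarray
    inv_rest_shape: np.ndarray  # 3x3, inverse of the rest edge matrix D_m
    rest_volume: float
    alpha_h: float = 0.0
    alpha_d: float = 0.0
    rest_offset: float = 0.0
    lambda_h: float = 0.0
    lambda_d: float = 0.0


@dataclass
class ShapeMatchCluster:
    """Particle cluster pulled toward its best-fit rigid transform."""

    member_ids: np.ndarray
    rest_offsets: np.ndarray  # rest positions relative to rest mass-center
    member_masses: np.ndarray
    stiffness: float = 1.0
    prev_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))


# ---------------------------------------------------------------------------
# Constraint evaluation: value and per-vertex gradients
# ---------------------------------------------------------------------------


def eval_distance(c: DistanceConstraint, positions: np.ndarray):
    """Value |x_i - x_j| - d and unit gradients; None for coincident points."""
    diff = positions[c.i] - positions[c.j]
    dist = float(np.linalg.norm(diff))
    if dist < DEGENERATE_TOL:
        log.debug("skipping degenerate distance constraint (%d, %d)", c.i, c.j)
        return None
    n = diff / dist
    return dist - c.rest_length, np.array([n, -n])


def eval_volume(c: VolumeConstraint, positions: np.ndarray):
    """Signed-volume constraint value and cofactor gradients (they sum to 0)."""
    x1, x2, x3, x4 = positions[c.ids]
    e1, e2, e3 = x2 - x1, x3 - x1, x4 - x1
    value = float(np.cross(e1, e2) @ e3) / 6.0 - c.rest_volume
    g2 = np.cross(e2, e3) / 6.0
    g3 = np.cross(e3, e1) / 6.0
    g4 = np.cross(e1, e2) / 6.0
    g1 = -(g2 + g3 + g4)
    return value, np.array([g1, g2, g3, g4])


def rest_shape_matrix(positions: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Rest edge matrix D_m with columns (x2-x1, x3-x1, x4-x1)."""
    x = positions[ids]
    return np.column_stack([x[1] - x[0], x[2] - x[0], x[3] - x[0]])


def deformation_gradient(c: TetElasticConstraint, positions: np.ndarray) -> np.ndarray:
    """F = D_s * D_m^-1 mapping the rest element shape to the current one."""
    return rest_shape_matrix(positions, c.ids) @ c.inv_rest_shape


def _chain_to_vertices(dC_dF: np.ndarray, inv_rest_shape: np.ndarray) -> np.ndarray:
    """Map dC/dF to per-vertex gradients through D_s = F-chain; grads sum to 0."""
    G = dC_dF @ inv_rest_shape.T  # columns = gradients at vertices 2, 3, 4
    g234 = G.T
    g1 = -g234.sum(axis=0)
    return np.vstack([g1, g234])


def _cofactor(F: np.ndarray) -> np.ndarray:
    f1, f2, f3 = F[:, 0], F[:, 1], F[:, 2]
    return np.column_stack([np.cross(f2, f3), np.cross(f3, f1), np.cross(f1, f2)])


def eval_neo_hydrostatic(c: TetElasticConstraint, positions: np.ndarray):
    """C_H = det(F) - 1 - rest_offset with cofactor-matrix gradient."""
    F = deformation_gradient(c, positions)
    value = float(np.linalg.det(F)) - 1.0 - c.rest_offset
    return value, _chain_to_vertices(_cofactor(F), c.inv_rest_shape)


def eval_neo_deviatoric(c: TetElasticConstraint, positions: np.ndarray):
    """C_D = sqrt(tr(F^T F)) = ||F||_F with gradient F / C_D; None if collapsed."""
    F = deformation_gradient(c, positions)
    value = float(np.sqrt((F * F).sum()))
    if value < 1e-8:
        log.debug("skipping collapsed tet-elastic constraint %s", c.ids)
        return None
    return value, _chain_to_vertices(F / value, c.inv_rest_shape)


# ---------------------------------------------------------------------------
# Shape matching
# ---------------------------------------------------------------------------


def polar_rotation(A: np.ndarray) -> np.ndarray | None:
    """Rotation factor of the polar decomposition of A with det = +1.

    Returns None when A is rank-deficient enough that the rotation is not
    determined (two or more vanishing singular values).
    """
    U, s, Vt = np.linalg.svd(A)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        return None
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        return None
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def best_fit_transform(cluster: ShapeMatchCluster, positions: np.ndarray):
    """Best-fit rigid transform (R, T) of the cluster via polar decomposition.

    T is the current mass-center; R is the polar rotation of the mass-weighted
    covariance A = sum_i m_i (x_i - T) q_i^T with rest offsets q_i.  Falls back
    to the previously returned rotation when A is rank-deficient.
    """
    m = cluster.member_masses
    x = positions[cluster.member_ids]
    T = (m[:, None] * x).sum(axis=0) / m.sum()
    A = (m[:, None] * (x - T)).T @ cluster.rest_offsets
    R = polar_rotation(A)
    if R is None:
        log.debug("rank-deficient shape-match covariance; reusing previous rotation")
        R = cluster.prev_rotation.copy()
    else:
        cluster.prev_rotation = R
    return R, T


def shape_match_corrections(cluster: ShapeMatchCluster, positions: np.ndarray) -> np.ndarray:
    """Blended positional corrections dx_i = k (R q_i + T - x_i).

    The mass-weighted sum of the corrections is exactly zero, so applying
    them conserves linear momentum of the cluster.
    """
    R, T = best_fit_transform(cluster, positions)
    goals = cluster.rest_offsets @ R.T + T
    return cluster.stiffness * (goals - positions[cluster.member_ids])


# ---------------------------------------------------------------------------
# XPBD update rules
# ---------------------------------------------------------------------------


def xpbd_delta_lambda(
    value: float,
    gradients: np.ndarray,
    inv_masses: np.ndarray,
    alpha_tilde: float,
    lambda_acc: float,
) -> float | None:
    """Multiplier increment; None when every involved vertex is pinned (hard)."""
    denom = float((inv_masses * (gradients * gradients).sum(axis=1)).sum()) + alpha_tilde
    if denom < DEGENERATE_TOL:
        return None
    return (-value - alpha_tilde * lambda_acc) / denom


def apply_position_update(
    delta_lambda: float,
    gradients: np.ndarray,
    inv_masses: np.ndarray,
    positions: np.ndarray,
    ids: np.ndarray,
) -> None:
    """In-place x_k += w_k * grad_k * dlambda; pinned vertices (w=0) unmoved."""
    positions[ids] += (inv_masses[:, None] * gradients) * delta_lambda


def project_constraint(
    c,
    positions: np.ndarray,
    inv_mass: np.ndarray,
    h: float,
    kind: str = "auto",
) -> None:
    """One XPBD Gauss-Seidel visit of a single constraint record (reference path)."""
    if isinstance(c, DistanceConstraint):
        res = eval_distance(c, positions)
        ids = np.array([c.i, c.j])
    elif isinstance(c, VolumeConstraint):
        res = eval_volume(c, positions)
        ids = c.ids
    elif isinstance(c, TetElasticConstraint):
        which = kind if kind != "auto" else "hydro"
        res = (eval_neo_hydrostatic if which == "hydro" else eval_neo_deviatoric)(c, positions)
        ids = c.ids
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a compliant constraint: {type(c)}")
    if res is None:
        return
    value, grads = res
    if isinstance(c, TetElasticConstraint):
        alpha = c.alpha_h if (kind in ("auto", "hydro")) else c.alpha_d
        lam = c.lambda_h if (kind in ("auto", "hydro")) else c.lambda_d
    else:
        alpha = c.alpha
        lam = c.lambda_acc
    if not np.isfinite(alpha):
        return  # infinitely compliant: constraint disabled
    at = alpha / (h * h)
    dl = xpbd_delta_lambda(value, grads, inv_mass[ids], at, lam)
    if dl is None:
        return
    apply_position_update(dl, grads, inv_mass[ids], positions, ids)
    if isinstance(c, TetElasticConstraint):
        if kind in ("auto", "hydro"):
            c.lambda_h += dl
        else:
            c.lambda_d += dl
    else:
        c.lambda_acc += dl


# ---------------------------------------------------------------------------
# ConstraintSet: packed arrays for the solver kernels
# ---------------------------------------------------------------------------


@dataclass
class ConstraintSet:
    """Typed constraint arrays built from a mesh and a material.

    Empty families have zero-length arrays; the solver skips them.
    """

    # distance
    d_ids: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    d_rest: np.ndarray = field(default_factory=lambda: np.zeros(0))
    d_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    d_lambda: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # volume
    v_ids: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), np.int64))
    v_rest: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v_lambda: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # tet-elastic (Neo-Hookean)
    t_ids: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), np.int64))
    t_inv_rest: np.ndarray = field(default_factory=lambda: np.zeros((0, 3, 3)))
    t_rest_vol: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_alpha_h: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_alpha_d: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_lambda_h: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_lambda_d: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # shape matching
    clusters: list = field(default_factory=list)

    def reset_lambdas(self) -> None:
        self.d_lambda[:] = 0.0
        self.v_lambda[:] = 0.0
        self.t_lambda_h[:] = 0.0
        self.t_lambda_d[:] = 0.0

    @property
    def counts(self) -> dict:
        return {
            "distance": len(self.d_rest),
            "volume": len(self.v_rest),
            "tet_elastic": len(self.t_rest_vol),
            "shape_clusters": len(self.clusters),
        }


def _grid_clusters(mesh: TetMesh, cells_per_axis: int) -> list[np.ndarray]:
    """Partition vertices into a regular grid of clusters over the bounding box."""
    lo = mesh.rest_positions.min(axis=0)
    hi = mesh.rest_positions.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    cell = np.minimum(
        (mesh.rest_positions - lo) / span * cells_per_axis, cells_per_axis - 1
    ).astype(int)
    key = (cell[:, 0] * cells_per_axis + cell[:, 1]) * cells_per_axis + cell[:, 2]
    groups: dict[int, list[int]] = {}
    for v, k in enumerate(key):
        groups.setdefault(int(k), []).append(v)
    big = {k: np.asarray(g, np.int64) for k, g in groups.items() if len(g) >= 4}
    if not big:
        return [np.arange(len(key), dtype=np.int64)]
    # Clusters need >= 4 non-collinear members to define a rotation; merge
    # undersized cells into the nearest large cluster so every vertex is covered.
    centroids = {k: mesh.rest_positions[g].mean(axis=0) for k, g in big.items()}
    merged = dict(big)
    for k, g in groups.items():
        if len(g) >= 4:
            continue
        small_centroid = mesh.rest_positions[g].mean(axis=0)
        nearest = min(
            centroids, key=lambda kk: float(np.sum((centroids[kk] - small_centroid) ** 2))
        )
        merged[nearest] = np.concatenate([merged[nearest], np.asarray(g, np.int64)])
    return [merged[k] for k in sorted(merged)]


def make_cluster(mesh: TetMesh, member_ids: np.ndarray, stiffness: float) -> ShapeMatchCluster:
    m = mesh.vertex_mass[member_ids]
    x0 = mesh.rest_positions[member_ids]
    com = (m[:, None] * x0).sum(axis=0) / m.sum()
    return ShapeMatchCluster(
        member_ids=member_ids,
        rest_offsets=x0 - com,
        member_masses=m,
        stiffness=stiffness,
    )


def build_constraints(
    mesh: TetMesh,
    material: Material,
    *,
    distance: bool = True,
    volume: bool = True,
    neo: bool = True,
    shape_matching: bool = False,
    shape_clusters: str = "global",
    cluster_cells: int = 2,
    shape_stiffness: float | None = None,
    rest_correction: bool = False,
) -> ConstraintSet:
    """Generate the constraint set for a mesh: distance per unique edge, volume
    and tet-elastic per tet, shape-match clusters per the cluster spec."""
    cs = ConstraintSet()
    if distance:
        cs.d_ids = mesh.edges.astype(np.int64)
        cs.d_rest = np.linalg.norm(
            mesh.rest_positions[cs.d_ids[:, 0]] - mesh.rest_positions[cs.d_ids[:, 1]], axis=1
        )
        cs.d_alpha = np.array([material.distance_compliance(L) for L in cs.d_rest])
        cs.d_lambda = np.zeros(len(cs.d_rest))
    if volume:
        cs.v_ids = mesh.tets.astype(np.int64)
        cs.v_rest = mesh.rest_volumes.copy()
        cs.v_alpha = np.array([material.volume_compliance(V) for V in cs.v_rest])
        cs.v_lambda = np.zeros(len(cs.v_rest))
    if neo:
        cs.t_ids = mesh.tets.astype(np.int64)
        cs.t_rest_vol = mesh.rest_volumes.copy()
        Dm = np.stack([rest_shape_matrix(mesh.rest_positions, t) for t in mesh.tets])
        cs.t_inv_rest = np.linalg.inv(Dm)
        ah_ad = np.array([element_compliances(material, V) for V in cs.t_rest_vol])
        cs.t_alpha_h = ah_ad[:, 0]
        cs.t_alpha_d = ah_ad[:, 1]
        offset = material.lame_mu / material.lame_lambda if (
            rest_correction and material.lame_lambda > 0
        ) else 0.0
        cs.t_offset = np.full(len(cs.t_rest_vol), offset)
        cs.t_lambda_h = np.zeros(len(cs.t_rest_vol))
        cs.t_lambda_d = np.zeros(len(cs.t_rest_vol))
    if shape_matching:
        k = material.shape_stiffness if shape_stiffness is None else shape_stiffness
        if shape_clusters == "global":
            groups = [np.arange(mesh.n_vertices, dtype=np.int64)]
        elif shape_clusters == "grid":
            groups = _grid_clusters(mesh, cluster_cells)
        else:
            raise ValueError(f"unknown shape cluster spec {shape_clusters!r}")
        cs.clusters = [make_cluster(mesh, g, k) for g in groups]
    return cs
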