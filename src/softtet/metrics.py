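"""Quantitative observables of a running simulation.

The central quantity is the mesh-smoothness metric

    S = (1/n) * sum_i  V_min,i / V_max,i

over the n face-adjacent tetrahedron pairs, where V_min/V_max are the
smaller and larger absolute volumes of the pair.  S is dimensionless in
(0, 1]; S = 1 means every adjacent pair has equal volume, and lower values
indicate locally uneven (spiky, distorted) elements.  The reported spread is
the population standard deviation of the per-pair ratios.

Also provided: relative total-volume drift, kinetic energy, maximum collider
penetration, and RMS constraint residuals per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .constraints import ConstraintSet
from .tet_mesh import TetMesh, signed_volumes

__all__ = [
    "MetricRecord",
    "adjacent_element_pairs",
    "smoothness",
    "volume_drift",
    "kinetic_energy",
    "max_penetration",
    "residual_norms",
    "MetricsObserver",
    "METRIC_COLUMNS",
]


@dataclass
class MetricRecord:
    frame: int
    time: float = 0.0
    smoothness_mean: float = np.nan
    smoothness_std: float = np.nan
    total_volume: float = np.nan
    volume_drift: float = np.nan
    kinetic_energy: float = np.nan
    max_penetration: float = 0.0
    inverted_tets: int = 0
    residual_distance: float = np.nan
    residual_volume: float = np.nan
    residual_neo_h: float = np.nan
    residual_neo_d: float = np.nan


METRIC_COLUMNS = [f.name for f in fields(MetricRecord)]


def adjacent_element_pairs(mesh: TetMesh) -> np.ndarray:
    """Unordered pairs of tet indices sharing a triangular face."""
    faces = {}
    pairs = []
    for t, tet in enumerate(mesh.tets):
        for omit in range(4):
            key = tuple(sorted(np.delete(tet, omit)))
            other = faces.pop(key, None)
            if other is None:
                faces[key] = t
            else:
                pairs.append((other, t))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def smoothness(
    mesh: TetMesh, positions: np.ndarray, pairs: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean and population std of the min/max volume ratio over adjacent pairs.

    Volumes enter as absolute values, so inverted elements degrade S instead
    of producing negative or >1 ratios.  Pairs in which both tets have
    collapsed to (near) zero volume are skipped.
    """
    if pairs is None:
        pairs = adjacent_element_pairs(mesh)
    if len(pairs) == 0:
        raise ValueError("smoothness needs at least one face-adjacent tet pair")
    vols = np.abs(signed_volumes(positions, mesh.tets))
    va, vb = vols[pairs[:, 0]], vols[pairs[:, 1]]
    vmax = np.maximum(va, vb)
    ok = vmax > 1e-300
    ratio = np.minimum(va, vb)[ok] / vmax[ok]
    if ratio.size == 0:
        raise ValueError("all adjacent pairs degenerate; smoothness undefined")
    return float(ratio.mean()), float(ratio.std())


def volume_drift(mesh: TetMesh, positions: np.ndarray) -> float:
    """Relative drift of total absolute volume from the rest total."""
    rest = mesh.rest_volumes.sum()
    current = np.abs(signed_volumes(positions, mesh.tets)).sum()
    return float((current - rest) / rest)


def inverted_count(mesh: TetMesh, positions: np.ndarray) -> int:
    return int((signed_volumes(positions, mesh.tets) < 0).sum())


def kinetic_energy(mesh: TetMesh, velocities: np.ndarray) -> float:
    return float(0.5 * (mesh.vertex_mass * (velocities**2).sum(axis=1)).sum())


def max_penetration(positions: np.ndarray, colliders: list, thickness: float = 0.0) -> float:
    """Deepest penetration past the contact thickness surface (0 if none)."""
    worst = 0.0
    for shape in colliders:
        d = shape.query_batch(positions)[0]
        worst = max(worst, float(np.maximum(thickness - d, 0.0).max()))
    return worst


def residual_norms(constraints: ConstraintSet, positions: np.ndarray) -> dict:
    """RMS constraint values per family at the given positions."""
    out = {}
    if len(constraints.d_rest):
        d = np.linalg.norm(
            positions[constraints.d_ids[:, 0]] - positions[constraints.d_ids[:, 1]], axis=1
        )
        out["distance"] = float(np.sqrt(np.mean((d - constraints.d_rest) ** 2)))
    if len(constraints.v_rest):
        p = positions[constraints.v_ids]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        out["volume"] = float(np.sqrt(np.mean((v - constraints.v_rest) ** 2)))
    if len(constraints.t_rest_vol):
        p = positions[constraints.t_ids]
        Ds = np.stack(
            [p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=-1
        )
        F = Ds @ constraints.t_inv_rest
        det = np.linalg.det(F)
        out["neo_h"] = float(
            np.sqrt(np.mean((det - 1.0 - constraints.t_offset) ** 2))
        )
        out["neo_d"] = float(np.sqrt(np.mean((F**2).sum(axis=(1, 2)))))
    return out


class MetricsObserver:
    """Observer for :func:`softtet.solver.run` producing one MetricRecord per frame."""

    def __init__(
        self,
        mesh: TetMesh,
        constraints: ConstraintSet | None = None,
        colliders: list | None = None,
        thickness: float = 0.0,
    ):
        self.mesh = mesh
        self.constraints = constraints
        self.colliders = colliders or []
        self.thickness = thickness
        self.pairs = adjacent_element_pairs(mesh)
        self.records: list[MetricRecord] = []

    def __call__(self, frame: int, state) -> MetricRecord:
        rec = MetricRecord(frame=frame, time=state.time)
        if len(self.pairs):
            rec.smoothness_mean, rec.smoothness_std = smoothness(
                self.mesh, state.positions, self.pairs
            )
        vols = signed_volumes(state.positions, self.mesh.tets)
        rec.total_volume = float(np.abs(vols).sum())
        rec.volume_drift = float(
            (rec.total_volume - self.mesh.rest_volumes.sum()) / self.mesh.rest_volumes.sum()
        )
        rec.inverted_tets = int((vols < 0).sum())
        rec.kinetic_energy = kinetic_energy(self.mesh, state.velocities)
        if self.colliders:
            rec.max_penetration = max_penetration(
                state.positions, self.colliders, self.thickness
            )
        if self.constraints is not None:
            res = residual_norms(self.constraints, state.positions)
            rec.residual_distance = res.get("distance", np.nan)
            rec.residual_volume = res.get("volume", np.nan)
            rec.residual_neo_h = res.get("neo_h", np.nan)
            rec.residual_neo_d = res.get("neo_d", np.nan)
        self.records.append(rec)
        return rec

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records], columns=METRIC_COLUMNS)
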