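"""Signed-distance-field colliders and contact response.

Contacts are vertex-vs-SDF only.  Each shape answers a signed-distance query
(negative strictly inside) with an outward unit normal.  Non-penetration is
a hard inequality constraint projected positionally; Coulomb-style friction
acts on the tangential displacement of the same substep; restitution acts on
the normal velocity after the velocity update.  An optional
continuous-collision query finds the earliest impact along a motion segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SDFShape",
    "Plane",
    "Sphere",
    "Box",
    "Contact",
    "sdf_query",
    "detect_contacts",
    "project_contact",
    "apply_friction",
    "contact_velocity_response",
    "ccd_toi",
]


@dataclass
class SDFShape:
    friction_coeff: float = 0.0
    restitution: float = 0.0

    def query(self, point: np.ndarray) -> tuple[float, np.ndarray]:
        d, n = self.query_batch(np.asarray(point, float).reshape(1, 3))
        return float(d[0]), n[0]

    def query_batch(self, points: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class Plane(SDFShape):
    """Half-space collider: d = (p - point) . normal."""

    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        n = np.asarray(self.normal, float)
        self.normal = n / np.linalg.norm(n)

    def query_batch(self, points: np.ndarray):
        d = (points - self.point) @ self.normal
        n = np.broadcast_to(self.normal, points.shape).copy()
        return d, n


@dataclass
class Sphere(SDFShape):
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, float)

    def query_batch(self, points: np.ndarray):
        rel = points - self.center
        r = np.linalg.norm(rel, axis=1)
        d = r - self.radius
        safe = np.maximum(r, 1e-12)
        n = rel / safe[:, None]
        n[r < 1e-12] = np.array([0.0, 1.0, 0.0])  # center: arbitrary but unit
        return d, n


@dataclass
class Box(SDFShape):
    """Oriented box; standard rounded-box signed distance."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    half_extents: np.ndarray = field(default_factory=lambda: np.ones(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.half_extents = np.asarray(self.half_extents, float)
        self.rotation = np.asarray(self.rotation, float)

    def _sdf(self, points: np.ndarray) -> np.ndarray:
        local = (points - self.center) @ self.rotation
        q = np.abs(local) - self.half_extents
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
        inside = np.minimum(q.max(axis=1), 0.0)
        return outside + inside

    def query_batch(self, points: np.ndarray):
        d = self._sdf(points)
        # Gradient by central differences of the exact SDF (robust at edges
        # and inside, where the analytic branch splits).
        h = 1e-6 * max(1.0, float(self.half_extents.max()))
        grad = np.empty_like(points)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            grad[:, k] = (self._sdf(points + dp) - self._sdf(points - dp)) / (2 * h)
        norm = np.maximum(np.linalg.norm(grad, axis=1), 1e-12)
        return d, grad / norm[:, None]


@dataclass
class Contact:
    vertex: int
    shape: SDFShape
    depth: float  # penetration past the contact thickness, >= 0
    normal: np.ndarray

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("contact depth must be non-negative")


def sdf_query(shape: SDFShape, point: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed distance and outward unit normal of a single point."""
    return shape.query(point)


def detect_contacts(
    positions: np.ndarray, shapes: list[SDFShape], thickness: float = 0.0
) -> list[Contact]:
    """One Contact per (vertex, shape) pair closer than the contact thickness."""
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    contacts: list[Contact] = []
    for shape in shapes:
        d, n = shape.query_batch(positions)
        for v in np.flatnonzero(d < thickness):
            contacts.append(Contact(int(v), shape, float(thickness - d[v]), n[v].copy()))
    return contacts


def project_contact(contact: Contact, positions: np.ndarray, inv_masses: np.ndarray) -> None:
    """Hard non-penetration projection: move the vertex onto the thickness surface."""
    if contact.depth <= 0 or inv_masses[contact.vertex] == 0.0:
        return
    positions[contact.vertex] += contact.normal * contact.depth


def apply_friction(
    contact: Contact,
    positions: np.ndarray,
    prev_positions: np.ndarray,
    friction_coeff: float,
) -> None:
    """Coulomb-style positional friction on this substep's tangential slide.

    The tangential displacement is cancelled entirely when shorter than
    mu * (normal correction) (static stick), otherwise shortened by that
    amount (kinetic slip).
    """
    if friction_coeff <= 0 or contact.depth <= 0:
        return
    v = contact.vertex
    disp = positions[v] - prev_positions[v]
    n = contact.normal
    disp_t = disp - (disp @ n) * n
    slide = np.linalg.norm(disp_t)
    limit = friction_coeff * contact.depth
    if slide < 1e-15:
        return
    if slide <= limit:
        positions[v] -= disp_t
    else:
        positions[v] -= disp_t * (limit / slide)


def contact_velocity_response(
    contact: Contact,
    velocities: np.ndarray,
    restitution: float,
    normal_speed_before: float,
) -> None:
    """Restitution: reflect the pre-solve approaching normal velocity.

    ``normal_speed_before`` is v . n at substep start; only approaching
    contacts (negative) rebound.  The tangential component is untouched.
    """
    if normal_speed_before >= 0:
        return
    v = contact.vertex
    n = contact.normal
    vn = velocities[v] @ n
    velocities[v] += n * (-restitution * normal_speed_before - vn)


def ccd_toi(
    prev_point: np.ndarray,
    point: np.ndarray,
    shape: SDFShape,
    thickness: float = 0.0,
    tol: float = 1e-8,
) -> float | None:
    """Earliest impact fraction in [0, 1] along the segment, or None.

    Planes are solved exactly; other shapes by bisection on the SDF.
    """
    p0 = np.asarray(prev_point, float)
    p1 = np.asarray(point, float)
    d0 = shape.query(p0)[0] - thickness
    d1 = shape.query(p1)[0] - thickness
    if d0 < 0:
        return 0.0
    if isinstance(shape, Plane):
        if d1 >= 0:
            return None
        return float(d0 / (d0 - d1))
    seg = float(np.linalg.norm(p1 - p0))
    if seg < 1e-15:
        return None
    if d1 < 0:
        # Endpoint inside: bisect the sign change directly.
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if shape.query(p0 + mid * (p1 - p0))[0] - thickness < 0:
                hi = mid
            else:
                lo = mid
        return float(0.5 * (lo + hi))
    # Both endpoints outside: sphere-trace along the segment.  The SDF is
    # 1-Lipschitz, so stepping by d(t) can never skip a crossing — this
    # catches fast tunnelling through geometry thinner than the motion.
    t = 0.0
    for _ in range(256):
        d = shape.query(p0 + t * (p1 - p0))[0] - thickness
        if d <= tol:
            return float(t)
        t += d / seg
        if t >= 1.0:
            return None
    return None
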