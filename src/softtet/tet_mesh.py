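"""Tetrahedral mesh data model, I/O and synthetic phantom generation.

The mesh is the static skeleton of a simulation: rest geometry, topology
(edges, surface), per-tet rest volumes and lumped vertex masses.  All
quantities are SI (metres, kilograms).  Vertex indexing is 0-based
internally regardless of the file dialect the mesh came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TetMesh",
    "MeshError",
    "load_mesh",
    "save_mesh",
    "compute_rest_volumes",
    "lump_masses",
    "make_box_phantom",
    "make_ellipsoid_phantom",
]


class MeshError(ValueError):
    """Raised for malformed mesh files or invalid mesh topology."""


# Faces of tet (a, b, c, d), oriented outward when the signed volume
# (1/6)((b-a) x (c-a)) . (d-a) is positive.
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])

_TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def signed_volumes(positions: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume (1/6)(x21 x x31) . x41 of each tet under the stored order."""
    p = positions[tets]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    e3 = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0


def compute_rest_volumes(mesh: "TetMesh") -> np.ndarray:
    """Per-tet rest volume; raises :class:`MeshError` on degenerate tets."""
    vols = signed_volumes(mesh.rest_positions, mesh.tets)
    degenerate = np.flatnonzero(vols == 0.0)
    if degenerate.size:
        raise MeshError(f"degenerate (zero-volume) tets at indices {degenerate.tolist()}")
    return vols


def _unique_edges(tets: np.ndarray) -> np.ndarray:
    e = tets[:, _TET_EDGES].reshape(-1, 2)
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _surface_faces(tets: np.ndarray) -> np.ndarray:
    """Faces that belong to exactly one tet, keeping outward orientation."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    keys = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 2):
        raise MeshError("invalid mesh: a face is shared by more than two tets")
    return faces[counts[inverse] == 1]


def lump_masses(mesh: "TetMesh", density: float) -> np.ndarray:
    """Lumped vertex masses: each tet adds one quarter of its mass to each corner."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    mass = np.zeros(len(mesh.rest_positions))
    quarter = density * mesh.rest_volumes / 4.0
    for corner in range(4):
        np.add.at(mass, mesh.tets[:, corner], quarter)
    return mass


@dataclass
class TetMesh:
    """Tetrahedral mesh with derived topology and lumped masses.

    ``inv_mass[i] == 0`` encodes a pinned (kinematically fixed) vertex.
    """

    rest_positions: np.ndarray
    tets: np.ndarray
    edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    surface_tris: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    rest_volumes: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vertex_mass: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    inv_mass: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    density: float = 1000.0

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        tets: np.ndarray,
        *,
        density: float = 1000.0,
        pinned: np.ndarray | list | None = None,
    ) -> "TetMesh":
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)
        if tets.size and (tets.min() < 0 or tets.max() >= len(positions)):
            raise MeshError("tet vertex index out of range")
        # Repair negative-volume tets by swapping indices 1 and 2.
        vols = signed_volumes(positions, tets)
        flipped = np.flatnonzero(vols < 0)
        if flipped.size:
            log.info("repairing %d negative-volume tets by swapping indices 1<->2", flipped.size)
            tets = tets.copy()
            tets[flipped, 1], tets[flipped, 2] = (
                tets[flipped, 2].copy(),
                tets[flipped, 1].copy(),
            )
        mesh = cls(rest_positions=positions, tets=tets, density=density)
        mesh.rest_volumes = compute_rest_volumes(mesh)
        mesh.edges = _unique_edges(tets)
        mesh.surface_tris = _surface_faces(tets)
        mesh.vertex_mass = lump_masses(mesh, density)
        mesh.inv_mass = np.where(mesh.vertex_mass > 0, 1.0 / np.maximum(mesh.vertex_mass, 1e-300), 0.0)
        if pinned is not None:
            mesh.pin(pinned)
        return mesh

    @property
    def n_vertices(self) -> int:
        return len(self.rest_positions)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def total_volume(self) -> float:
        return float(self.rest_volumes.sum())

    def pin(self, indices: np.ndarray | list) -> None:
        """Fix the given vertices in place (inverse mass set to zero)."""
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_vertices):
            raise MeshError("pinned vertex index out of range")
        self.inv_mass[idx] = 0.0

    @property
    def pinned(self) -> np.ndarray:
        return np.flatnonzero(self.inv_mass == 0.0)


# ---------------------------------------------------------------------------
# File I/O: TetGen .node/.ele, legacy ASCII VTK, OBJ surface export
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> list[list[str]]:
    out = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append((ln, line.split()))
    return out


def _load_tetgen(path: Path, density: float) -> TetMesh:
    stem = path.with_suffix("")
    node_path, ele_path = stem.with_suffix(".node"), stem.with_suffix(".ele")
    for p in (node_path, ele_path):
        if not p.exists():
            raise MeshError(f"TetGen sibling file missing: {p}")

    lines = _data_lines(node_path)
    try:
        n_pts = int(lines[0][1][0])
    except (IndexError, ValueError) as exc:
        raise MeshError(f"{node_path}: malformed header at line {lines[0][0] if lines else 1}") from exc
    if len(lines) - 1 < n_pts:
        raise MeshError(f"{node_path}: header promises {n_pts} points, found {len(lines) - 1}")
    first_index = None
    ids, coords = [], []
    for ln, toks in lines[1 : 1 + n_pts]:
        try:
            ids.append(int(toks[0]))
            coords.append([float(t) for t in toks[1:4]])
        except (IndexError, ValueError) as exc:
            raise MeshError(f"{node_path}: malformed node record at line {ln}") from exc
    first_index = min(ids)
    if first_index not in (0, 1):
        raise MeshError(f"{node_path}: node indices must start at 0 or 1, got {first_index}")
    order = np.argsort(ids)
    positions = np.asarray(coords)[order]

    lines = _data_lines(ele_path)
    try:
        n_tets = int(lines[0][1][0])
    except (IndexError, ValueError) as exc:
        raise MeshError(f"{ele_path}: malformed header at line {lines[0][0] if lines else 1}") from exc
    tets = []
    for ln, toks in lines[1 : 1 + n_tets]:
        try:
            tets.append([int(t) - first_index for t in toks[1:5]])
        except (IndexError, ValueError) as exc:
            raise MeshError(f"{ele_path}: malformed tet record at line {ln}") from exc
    return TetMesh.from_arrays(positions, np.asarray(tets), density=density)


def _load_vtk(path: Path, density: float) -> TetMesh:
    tokens: list[str] = []
    line_of: list[int] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        for t in raw.split():
            tokens.append(t)
            line_of.append(ln)
    upper = [t.upper() for t in tokens]

    def find(keyword: str) -> int:
        try:
            return upper.index(keyword)
        except ValueError:
            raise MeshError(f"{path}: missing {keyword} section") from None

    if "UNSTRUCTURED_GRID" not in upper:
        raise MeshError(f"{path}: not an unstructured grid VTK file")
    i = find("POINTS")
    try:
        n_pts = int(tokens[i + 1])
        flat = [float(t) for t in tokens[i + 3 : i + 3 + 3 * n_pts]]
    except (IndexError, ValueError) as exc:
        raise MeshError(f"{path}: malformed POINTS near line {line_of[i]}") from exc
    if len(flat) != 3 * n_pts:
        raise MeshError(f"{path}: POINTS section truncated")
    positions = np.asarray(flat).reshape(-1, 3)

    i = find("CELLS")
    try:
        n_cells = int(tokens[i + 1])
        total = int(tokens[i + 2])
        body = [int(t) for t in tokens[i + 3 : i + 3 + total]]
    except (IndexError, ValueError) as exc:
        raise MeshError(f"{path}: malformed CELLS near line {line_of[i]}") from exc
    i = find("CELL_TYPES")
    try:
        types = [int(t) for t in tokens[i + 2 : i + 2 + n_cells]]
    except (IndexError, ValueError) as exc:
        raise MeshError(f"{path}: malformed CELL_TYPES near line {line_of[i]}") from exc
    if any(t != 10 for t in types):
        bad = next(t for t in types if t != 10)
        raise MeshError(f"{path}: unsupported cell type {bad} (only tetrahedra, VTK type 10)")
    tets, k = [], 0
    for _ in range(n_cells):
        npts = body[k]
        if npts != 4:
            raise MeshError(f"{path}: cell with {npts} points is not a tetrahedron")
        tets.append(body[k + 1 : k + 5])
        k += 1 + npts
    return TetMesh.from_arrays(positions, np.asarray(tets), density=density)


def load_mesh(path: str | Path, format: str = "auto", *, density: float = 1000.0) -> TetMesh:
    """Load a tetrahedral mesh from a TetGen .node/.ele pair or legacy ASCII VTK."""
    path = Path(path)
    if format == "auto":
        format = "tetgen" if path.suffix in (".node", ".ele") else "vtk"
    if format == "tetgen":
        return _load_tetgen(path, density)
    if format == "vtk":
        if not path.exists():
            raise MeshError(f"no such file: {path}")
        return _load_vtk(path, density)
    raise ValueError(f"unknown mesh format {format!r}")


def save_mesh(
    mesh: TetMesh,
    positions: np.ndarray,
    path: str | Path,
    format: str = "vtk",
) -> None:
    """Write the mesh at the given vertex positions (vtk volume or obj surface)."""
    positions = np.asarray(positions, dtype=np.float64)
    if positions.shape != (mesh.n_vertices, 3):
        raise ValueError(
            f"positions shape {positions.shape} does not match vertex count {mesh.n_vertices}"
        )
    path = Path(path)
    if format == "vtk":
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nsofttet tetrahedral mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {mesh.n_vertices} double\n")
            for p in positions:
                f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            f.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
            for t in mesh.tets:
                f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            f.write(f"CELL_TYPES {mesh.n_tets}\n")
            f.write("\n".join(["10"] * mesh.n_tets) + "\n")
    elif format == "obj_surface":
        with open(path, "w") as f:
            for p in positions:
                f.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for t in mesh.surface_tris:
                f.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    else:
        raise ValueError(f"unknown save format {format!r}")


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------

# The two mirror-image 5-tet splits of a hexahedral cell, indexing the local
# corner grid c[i,j,k] flattened as i*4 + j*2 + k.  The "even" split takes the
# central tet on corners with even coordinate-parity; the "odd" split mirrors
# it so the diagonals of shared faces between neighbouring cells coincide.
def _five_tet_splits() -> tuple[np.ndarray, np.ndarray]:
    def lid(i, j, k):
        return i * 4 + j * 2 + k

    even_corners = [(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
    odd_corners = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]

    def split(central):
        others = [c for c in
                  [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
                  if c not in central]
        tets = [[lid(*c) for c in central]]
        for b in others:
            neighbors = [c for c in central if sum(abs(x - y) for x, y in zip(b, c)) == 1]
            tets.append([lid(*b)] + [lid(*c) for c in neighbors])
        return np.asarray(tets)

    return split(even_corners), split(odd_corners)


_SPLIT_EVEN, _SPLIT_ODD = _five_tet_splits()


def _grid_cells_to_mesh(
    cells: np.ndarray,
    nx: int,
    ny: int,
    nz: int,
    extent: np.ndarray,
    origin: np.ndarray,
    density: float,
) -> TetMesh:
    """Turn a list of (i, j, k) hex cells of a structured grid into a TetMesh."""

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i, j, k in cells:
        split = _SPLIT_EVEN if (i + j + k) % 2 == 0 else _SPLIT_ODD
        corner_ids = np.array(
            [vid(i + a, j + b, k + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        )
        tets.append(corner_ids[split])
    tets = np.concatenate(tets)

    # Compact to the vertices actually used.
    used, inverse = np.unique(tets, return_inverse=True)
    tets = inverse.reshape(-1, 4)
    ii, rem = np.divmod(used, (ny + 1) * (nz + 1))
    jj, kk = np.divmod(rem, nz + 1)
    h = extent / np.array([nx, ny, nz], dtype=np.float64)
    positions = origin + np.column_stack([ii, jj, kk]) * h
    return TetMesh.from_arrays(positions, tets, density=density)


def make_box_phantom(
    nx: int,
    ny: int,
    nz: int,
    extent: tuple[float, float, float] = (1.0, 1.0, 1.0),
    *,
    density: float = 1000.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Structured box phantom: each hex cell split into 5 tets with parity flip.

    The total rest volume equals ``prod(extent)`` exactly.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("cell counts must be >= 1")
    cells = np.array([(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)])
    return _grid_cells_to_mesh(
        cells, nx, ny, nz, np.asarray(extent, float), np.asarray(origin, float), density
    )


def make_ellipsoid_phantom(
    semi_axes: tuple[float, float, float],
    resolution: int = 8,
    *,
    density: float = 1000.0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Voxelized ellipsoid ("liver-like") phantom.

    Keeps the grid cells of the bounding box whose centroids lie inside the
    ellipsoid, then splits each into 5 tets.  Raises :class:`MeshError` when
    the resolution is too coarse to keep any cell or the kept cells are not a
    single connected component.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi_axes must be positive")
    n = int(resolution)
    # Cubic cells sized by the largest semi-axis, so slender axes coarser
    # than one cell yield no interior centroids (an explicit error) instead
    # of silently producing arbitrarily flat elements.
    side = 2.0 * max(a, b, c)
    extent = np.array([side, side, side])
    origin = np.asarray(center, float) - extent / 2.0
    h = extent / n
    idx = np.arange(n)
    ci, cj, ck = np.meshgrid(idx, idx, idx, indexing="ij")
    centroids = origin + (np.stack([ci, cj, ck], axis=-1) + 0.5) * h
    rel = (centroids - np.asarray(center)) / np.array([a, b, c])
    inside = (rel**2).sum(axis=-1) <= 1.0
    cells = np.column_stack([ci[inside], cj[inside], ck[inside]])
    if len(cells) == 0:
        raise MeshError("resolution too coarse: no cell centroid falls inside the ellipsoid")
    mesh = _grid_cells_to_mesh(cells, n, n, n, extent, origin, density)
    if _n_components(mesh) != 1:
        raise MeshError("ellipsoid phantom is not a single connected component")
    return mesh


def _n_components(mesh: TetMesh) -> int:
    parent = np.arange(mesh.n_vertices)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for tet in mesh.tets:
        r = find(tet[0])
        for v in tet[1:]:
            parent[find(v)] = r
    roots = {find(v) for v in range(mesh.n_vertices)}
    return len(roots)
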