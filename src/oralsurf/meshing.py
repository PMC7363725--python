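"""Triangle meshes from binary masks: extraction, areas, repair, STL I/O.

Areas are accumulated internally in mm^2 and reported in cm^2, the unit of
the area tables this package produces.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .segmentation import BinaryMask

__all__ = [
    "TriangleMesh",
    "HoleFillReport",
    "StlParseError",
    "extract_isosurface",
    "mesh_area",
    "flat_fill_holes",
    "boundary_loops",
    "write_stl",
    "read_stl",
]

MM2_PER_CM2 = 100.0


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle mesh; vertices in world millimetres."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3))
        faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_areas_mm2(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float), self.faces)


def _empty_mesh() -> TriangleMesh:
    return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))


def extract_isosurface(
    mask: BinaryMask, level: float = 0.5, smooth_sigma_voxels: float = 1.0
) -> TriangleMesh:
    """Marching-cubes surface of a binary mask in world millimetres.

    The mask is converted to a float field and Gaussian-smoothed (default
    sigma 1 voxel) before contouring at ``level``; smoothing suppresses the
    staircase over-estimation of surface area inherent to voxelized shapes.
    The grid is zero-padded first so a mask touching nothing but interior
    voxels always yields a closed (watertight) surface.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"isosurface level must lie in (0, 1), got {level}")
    if mask.data.size == 0 or not mask.data.any():
        return _empty_mesh()
    pad = max(2, int(np.ceil(3 * smooth_sigma_voxels)))
    field_ = np.pad(mask.data, pad).astype(np.float32)
    if smooth_sigma_voxels > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=smooth_sigma_voxels)
    verts, faces, _, _ = measure.marching_cubes(field_, level=level, spacing=mask.spacing_mm)
    shift = np.asarray(mask.origin_mm) - pad * np.asarray(mask.spacing_mm)
    return TriangleMesh(verts + shift, faces)


def mesh_area(mesh: TriangleMesh, face_subset=None) -> float:
    """Total (or subset) triangle area in cm^2."""
    areas = mesh.face_areas_mm2()
    if face_subset is not None:
        idx = np.asarray(face_subset, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_faces):
            raise IndexError("face subset contains out-of-range indices")
        areas = areas[idx]
    return float(areas.sum()) / MM2_PER_CM2


class NonManifoldBoundaryError(ValueError):
    """Boundary topology that cannot be chained into simple loops."""


def boundary_loops(mesh: TriangleMesh) -> list[list[int]]:
    """Vertex-index loops of the open boundary (edges used by exactly one face).

    Raises :class:`NonManifoldBoundaryError` if an edge is shared by more
    than two faces or a boundary vertex has more than two boundary edges.
    """
    if mesh.n_faces == 0:
        return []
    edges = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    keys = np.sort(edges, axis=1)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    over = uniq[counts > 2]
    if len(over):
        raise NonManifoldBoundaryError(
            f"edge {tuple(over[0])} is shared by {counts[counts > 2][0]} faces"
        )
    boundary = uniq[counts == 1]
    if not len(boundary):
        return []
    adjacency: dict[int, list[int]] = {}
    for a, b in boundary:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    for v, nbrs in adjacency.items():
        if len(nbrs) != 2:
            raise NonManifoldBoundaryError(
                f"boundary vertex {v} has {len(nbrs)} boundary edges (expected 2)"
            )
    loops: list[list[int]] = []
    unvisited = set(adjacency)
    while unvisited:
        start = min(unvisited)
        loop = [start]
        unvisited.discard(start)
        prev, cur = None, start
        while True:
            nxt = [n for n in adjacency[cur] if n != prev]
            nxt = nxt[0] if nxt else adjacency[cur][0]
            if nxt == start:
                break
            loop.append(nxt)
            unvisited.discard(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


@dataclass(frozen=True)
class HoleFillReport:
    filled: tuple[tuple[int, float], ...] = field(default_factory=tuple)  # (n_verts, perimeter)
    skipped: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    @property
    def n_filled(self) -> int:
        return len(self.filled)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _loop_perimeter(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(points, -1, axis=0) - points, axis=1).sum())


def _boundary_edge_orientation(mesh: TriangleMesh, a: int, b: int) -> bool:
    """True if directed edge (a, b) appears in some face in that order."""
    fa = mesh.faces
    for i, j in ((0, 1), (1, 2), (2, 0)):
        if np.any((fa[:, i] == a) & (fa[:, j] == b)):
            return True
    return False


def flat_fill_holes(
    mesh: TriangleMesh, max_boundary_mm: float
) -> tuple[TriangleMesh, HoleFillReport]:
    """Close open boundary loops by a centroid fan on the loop's best-fit plane.

    Loops with perimeter greater than ``max_boundary_mm`` are left open and
    listed as skipped — the repair is meant for bounded acquisition defects
    (e.g. a palate clipped by the scan field of view), not arbitrary holes.
    Existing faces are never modified or removed.
    """
    loops = boundary_loops(mesh)
    if not loops:
        return mesh, HoleFillReport()
    new_vertices = [mesh.vertices]
    new_faces = [mesh.faces]
    next_index = mesh.n_vertices
    filled, skipped = [], []
    for loop in loops:
        pts = mesh.vertices[loop]
        perimeter = _loop_perimeter(pts)
        if perimeter > max_boundary_mm:
            skipped.append((len(loop), perimeter))
            continue
        centroid = pts.mean(axis=0)
        # project the centroid onto the loop's best-fit plane (it already
        # lies on it: the plane passes through the centroid by construction)
        new_vertices.append(centroid[None, :])
        # orient fan triangles against the existing winding of the border
        # edges so the patch matches the neighbouring faces
        fan = []
        n = len(loop)
        for i in range(n):
            a, b = loop[i], loop[(i + 1) % n]
            if _boundary_edge_orientation(mesh, a, b):
                fan.append((b, a, next_index))
            else:
                fan.append((a, b, next_index))
        new_faces.append(np.asarray(fan, dtype=np.int64))
        next_index += 1
        filled.append((len(loop), perimeter))
    out = TriangleMesh(np.vstack(new_vertices), np.vstack(new_faces))
    return out, HoleFillReport(tuple(filled), tuple(skipped))


# ---------------------------------------------------------------------------
# STL reading and writing


class StlParseError(ValueError):
    """Malformed STL input; the message carries the failing byte offset."""


_BINARY_HEADER = struct.Struct("<80sI")
_ASCII_VERTEX = re.compile(rb"vertex\s+([^\s]+)\s+([^\s]+)\s+([^\s]+)")


def write_stl(mesh: TriangleMesh, path: str | Path, ascii_dialect: bool = False) -> None:
    """Write a mesh as STL; binary by default, ASCII on request."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    cross = np.cross(
        tri[:, 1].astype(np.float64) - tri[:, 0], tri[:, 2].astype(np.float64) - tri[:, 0]
    )
    norms = np.linalg.norm(cross, axis=1)
    normals = np.divide(cross, norms[:, None], out=np.zeros_like(cross), where=norms[:, None] > 0)
    if ascii_dialect:
        lines = ["solid oralsurf"]
        for nrm, t in zip(normals, tri):
            lines.append(f"  facet normal {nrm[0]:e} {nrm[1]:e} {nrm[2]:e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid oralsurf\n")
        path.write_text("\n".join(lines))
        return
    record = np.zeros(
        len(tri),
        dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
    )
    record["normal"] = normals.astype(np.float32)
    record["v"] = tri
    with path.open("wb") as fh:
        fh.write(_BINARY_HEADER.pack(b"oralsurf binary STL", len(tri)))
        fh.write(record.tobytes())


def _weld(triangles: np.ndarray) -> TriangleMesh:
    """Index a triangle soup, merging bit-identical vertices."""
    flat = triangles.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    return TriangleMesh(vertices.astype(np.float64), inverse.reshape(-1, 3))


def read_stl(path: str | Path) -> TriangleMesh:
    """Read binary or ASCII STL; exact duplicate vertices are merged."""
    raw = Path(path).read_bytes()
    if len(raw) < _BINARY_HEADER.size:
        if raw.lstrip().startswith(b"solid") and b"facet" not in raw:
            if b"endsolid" in raw:  # empty ASCII solid
                return _empty_mesh()
        raise StlParseError(f"file too short for STL at byte {len(raw)}")
    is_ascii = raw.lstrip().startswith(b"solid") and b"facet" in raw[:2048]
    if not is_ascii and raw.lstrip().startswith(b"solid") and b"endsolid" in raw:
        is_ascii = True
    if is_ascii:
        coords = _ASCII_VERTEX.findall(raw)
        if b"endsolid" not in raw:
            raise StlParseError(f"ASCII STL truncated (no endsolid) at byte {len(raw)}")
        if len(coords) % 3:
            raise StlParseError(f"ASCII STL vertex count {len(coords)} is not a multiple of 3")
        if not coords:
            return _empty_mesh()
        triangles = np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)
        return _weld(triangles)
    _, count = _BINARY_HEADER.unpack_from(raw)
    expected = _BINARY_HEADER.size + 50 * count
    if len(raw) < expected:
        raise StlParseError(
            f"binary STL truncated: expected {expected} bytes for {count} facets, "
            f"got {len(raw)} (failure at byte {len(raw)})"
        )
    if count == 0:
        return _empty_mesh()
    record = np.frombuffer(
        raw,
        dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        count=count,
        offset=_BINARY_HEADER.size,
    )
    return _weld(record["v"].astype(np.float64))
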