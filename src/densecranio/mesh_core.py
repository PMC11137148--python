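"""Geometric types, mesh / landmark file I/O and elementary surface queries.

Everything downstream (wrapping, registration, landmark transfer) works on the
:class:`TriangleMesh` container defined here: vertices in millimetres, 0-based
triangular faces.  File parsing and serialisation are delegated to ``trimesh``;
the exact closest-point and ray-intersection kernels are implemented here on
top of a :class:`scipy.spatial.cKDTree` so that queries are exact (faces, edges
and vertices are all candidates), not vertex-only.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

MERGE_TOL = 1e-6  # duplicate-vertex merge tolerance, mm

__all__ = [
    "TriangleMesh",
    "LandmarkConfiguration",
    "MaskedShape",
    "SurfacePoint",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "closest_surface_point",
    "closest_surface_points",
    "project_points",
    "vertex_normals",
    "ray_surface_distance",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or is empty."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangle surface mesh in mm with 0-based face indexing.

    Construction cleans the input: duplicate vertices are merged within
    ``MERGE_TOL`` mm, zero-area faces are dropped, and coordinates must be
    finite.  ``normals``, when present, are unit per-vertex normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.size == 0:
            raise MeshFormatError("mesh has no vertices")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("mesh has non-finite vertex coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError("face index out of range")
        self._drop_degenerate_faces()
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)

    def _drop_degenerate_faces(self) -> None:
        if not len(self.faces):
            return
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        keep = areas > 1e-14
        dropped = int((~keep).sum())
        if dropped:
            log.info("dropped %d degenerate face(s)", dropped)
            self.faces = self.faces[keep]

    # -- derived quantities, cached -------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        tri = self.triangles
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def edges_unique(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_kdtree(self) -> cKDTree:
        if "vkd" not in self._cache:
            self._cache["vkd"] = cKDTree(self.vertices)
        return self._cache["vkd"]

    def _centroid_tree(self) -> tuple[cKDTree, float]:
        """KD-tree on face centroids plus the max centroid-to-corner radius.

        The radius makes pruned closest-point queries exact: any face whose
        surface could be nearer than the current best has its centroid within
        best + radius.
        """
        if "ckd" not in self._cache:
            tri = self.triangles
            cen = tri.mean(axis=1)
            rad = float(np.linalg.norm(tri - cen[:, None, :], axis=2).max())
            self._cache["ckd"] = (cKDTree(cen), rad)
        return self._cache["ckd"]

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(0), self.vertices.max(0)])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )

    def transformed(self, matrix_or_fn) -> "TriangleMesh":
        """Apply a 4x4 homogeneous matrix or a callable on vertex arrays."""
        if callable(matrix_or_fn):
            v = matrix_or_fn(self.vertices)
        else:
            m = np.asarray(matrix_or_fn, float)
            v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriangleMesh(v, self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class LandmarkConfiguration:
    """K named sparse landmarks (mm) living on one mesh / in one frame."""

    names: list[str]
    points: np.ndarray
    frame: str = ""

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(self.names) == 0:
            raise ValueError("need at least one landmark")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "LandmarkConfiguration":
        idx = [self.names.index(n) for n in names]
        return LandmarkConfiguration(list(names), self.points[idx], self.frame)


@dataclass
class MaskedShape:
    """A target expressed as the template's Q quasi-landmarks in correspondence.

    ``quasi`` rows share vertex identity across every individual masked with
    the same template; ``template_faces`` is the shared face list.
    """

    quasi: np.ndarray
    template_faces: np.ndarray

    def __post_init__(self) -> None:
        self.quasi = np.asarray(self.quasi, dtype=float).reshape(-1, 3)
        self.template_faces = np.asarray(self.template_faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.quasi).all():
            raise ValueError("quasi-landmarks must be finite")

    @property
    def n_quasi(self) -> int:
        return len(self.quasi)

    def as_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.quasi.copy(), self.template_faces.copy())


@dataclass
class SurfacePoint:
    """A point constrained to a mesh face, with barycentric coordinates."""

    position: np.ndarray
    face_id: int
    barycentric: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        self.barycentric = np.asarray(self.barycentric, float).reshape(3)
        if abs(self.barycentric.sum() - 1.0) > 1e-9 or (self.barycentric < -1e-9).any():
            raise ValueError("barycentric weights must be >= 0 and sum to 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"obj", "ply", "stl"}


def _infer_format(path: Path, fmt: str | None) -> str:
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {f!r} (use obj/ply/stl)")
    return f


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read an OBJ/PLY/STL mesh, merging duplicate vertices within 1e-6 mm.

    Vertex order is preserved for OBJ/PLY apart from merged duplicates.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(str(path), file_type=f, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - surface parser detail
        raise MeshFormatError(f"could not parse {path} as {f}: {exc}") from exc
    if tm.vertices is None or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    v = np.asarray(tm.vertices, float)
    fc = np.asarray(tm.faces, np.int64)
    v, fc = _merge_duplicate_vertices(v, fc, MERGE_TOL)
    return TriangleMesh(v, fc)


def _merge_duplicate_vertices(
    v: np.ndarray, f: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    # quantize on a grid finer than tol; first occurrence wins so order is kept
    key = np.round(v / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    remap = rank[inverse]
    vv = v[np.sort(first)]
    ff = remap[f] if len(f) else f
    if len(ff):
        ff = ff[(ff[:, 0] != ff[:, 1]) & (ff[:, 1] != ff[:, 2]) & (ff[:, 0] != ff[:, 2])]
    return vv, ff


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh; ``read_mesh(write_mesh(m))`` reproduces geometry within 1e-6 mm."""
    path = Path(path)
    f = _infer_format(path, fmt)
    tm = mesh.to_trimesh()
    try:
        tm.export(str(path), file_type=f)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc
    return path


def read_landmarks(path: str | Path, frame: str = "") -> LandmarkConfiguration:
    """Read landmarks from CSV (``name,x,y,z`` header) or JSON ``{name: [x,y,z]}``."""
    path = Path(path)
    names: list[str] = []
    pts: list[list[float]] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for name, xyz in data.items():
            names.append(name)
            pts.append([float(c) for c in xyz])
    else:
        with open(path, newline="") as fh:
            reader = csv.reader(row for row in fh if row.strip())
            header = next(reader)
            if [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
                raise ValueError(f"{path}: expected header 'name,x,y,z'")
            for row in reader:
                names.append(row[0])
                pts.append([float(c) for c in row[1:4]])
    return LandmarkConfiguration(names, np.asarray(pts), frame or str(path))


def write_landmarks(config: LandmarkConfiguration, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({n: list(map(float, p)) for n, p in zip(config.names, config.points)},
                       indent=1)
        )
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z"])
            for n, p in zip(config.names, config.points):
                w.writerow([n, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    return path


# ---------------------------------------------------------------------------
# closest point on surface
# ---------------------------------------------------------------------------


def _closest_point_pairwise(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point from each ``p[i]`` (M,3) to its triangle ``tri[i]`` (M,3,3).

    Returns (points (M,3), barycentric (M,3)).  Region-based algorithm
    (Ericson, Real-Time Collision Detection), vectorized elementwise.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    M = len(tri)
    u = np.zeros(M)
    v = np.zeros(M)
    done = np.zeros(M, bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    done |= m
    # vertex B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    u[m] = 1.0
    done |= m
    # vertex C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    v[m] = 1.0
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    u[m] = t[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    v[m] = t[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    u[m] = 1.0 - t[m]
    v[m] = t[m]
    done |= m
    # interior
    m = ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        u[m] = (vb / denom)[m]
        v[m] = (vc / denom)[m]

    w0 = 1.0 - u - v
    pts = w0[:, None] * a + u[:, None] * b + v[:, None] * c
    bary = np.stack([w0, u, v], axis=1)
    return pts, bary


def closest_surface_point(mesh: TriangleMesh, p: np.ndarray) -> SurfacePoint:
    """Exact closest point on the surface (faces, edges, vertices all candidates)."""
    return closest_surface_points(mesh, np.asarray(p, float).reshape(1, 3))[0]


def closest_surface_points(mesh: TriangleMesh, pts: np.ndarray) -> list[SurfacePoint]:
    """Batch exact closest-point query via a pruned KD-tree search."""
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    pts = np.asarray(pts, float).reshape(-1, 3)
    tree, rad = mesh._centroid_tree()
    tri = mesh.triangles
    k = min(16, mesh.n_faces)
    _, idx0 = tree.query(pts, k=k)
    idx0 = np.atleast_2d(idx0)
    out: list[SurfacePoint] = []
    for i, p in enumerate(pts):
        cand = idx0[i]
        cpts, bary = _closest_point_pairwise(np.broadcast_to(p, (len(cand), 3)), tri[cand])
        d = np.linalg.norm(cpts - p, axis=1)
        j = int(np.argmin(d))
        best = d[j]
        # exactness guard: fetch every face whose centroid is within best + rad
        extra = tree.query_ball_point(p, best + rad + 1e-12)
        extra = np.setdiff1d(np.asarray(extra, dtype=np.int64), cand)
        if len(extra):
            cpts2, bary2 = _closest_point_pairwise(
                np.broadcast_to(p, (len(extra), 3)), tri[extra]
            )
            d2 = np.linalg.norm(cpts2 - p, axis=1)
            j2 = int(np.argmin(d2))
            if d2[j2] < best:
                w2 = np.clip(bary2[j2], 0, None)
                out.append(SurfacePoint(cpts2[j2], int(extra[j2]), w2 / w2.sum()))
                continue
        w = np.clip(bary[j], 0, None)
        out.append(SurfacePoint(cpts[j], int(cand[j]), w / w.sum()))
    return out


def project_points(
    mesh: TriangleMesh, pts: np.ndarray, k: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fast batched surface projection onto the ``k`` nearest candidate faces.

    Near-exact on smooth meshes (candidates pruned by face-centroid KD-tree
    without the exhaustive guard of :func:`closest_surface_points`); used for
    registration correspondences where throughput matters.

    Returns (positions (N,k,3), distances (N,k), face_ids (N,k),
    barycentric (N,k,3)), candidates sorted by exact distance.
    """
    pts = np.asarray(pts, float).reshape(-1, 3)
    tree, _ = mesh._centroid_tree()
    k = min(k, mesh.n_faces)
    _, idx = tree.query(pts, k=k)
    idx = idx.reshape(len(pts), k)
    tri = mesh.triangles[idx]  # (N,k,3,3)
    N = len(pts)
    p_rep = np.repeat(pts, k, axis=0)
    cpts, bary = _closest_point_pairwise(p_rep, tri.reshape(N * k, 3, 3))
    cpts = cpts.reshape(N, k, 3)
    bary = bary.reshape(N, k, 3)
    d = np.linalg.norm(cpts - pts[:, None, :], axis=2)
    order = np.argsort(d, axis=1)
    rows = np.arange(N)[:, None]
    return cpts[rows, order], d[rows, order], idx[rows, order], bary[rows, order]


# ---------------------------------------------------------------------------
# normals
# ---------------------------------------------------------------------------


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Angle-weighted per-vertex unit normals, outward-oriented when closed.

    Isolated vertices get a zero normal (flagged via log warning).  Outward
    orientation is checked with the signed volume: a closed mesh stored with
    inward-facing winding gets its normals flipped globally.
    """
    fn = mesh.face_normals()
    V = mesh.n_vertices
    normals = np.zeros((V, 3))
    tri = mesh.triangles
    for c in range(3):
        e1 = tri[:, (c + 1) % 3] - tri[:, c]
        e2 = tri[:, (c + 2) % 3] - tri[:, c]
        cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, mesh.faces[:, c], fn * ang[:, None])
    lens = np.linalg.norm(normals, axis=1)
    iso = lens < 1e-14
    if iso.any():
        log.warning("%d isolated/degenerate vertex normals set to zero", int(iso.sum()))
    normals[~iso] /= lens[~iso, None]
    # orient outward for closed meshes
    boundary = _boundary_edge_count(mesh)
    if boundary == 0 and mesh.signed_volume() < 0:
        normals = -normals
    return normals


def _boundary_edge_count(mesh: TriangleMesh) -> int:
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return int((counts == 1).sum())


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def _ray_hits(origins: np.ndarray, direction_rows: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Per-ray nearest positive hit distance (inf when none).

    Möller–Trumbore, vectorized over faces, looped (chunked) over rays.
    """
    eps = 1e-12
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    out = np.full(len(origins), np.inf)
    for i in range(len(origins)):
        o, d = origins[i], direction_rows[i]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        # t >= 0 counts: a point lying on the surface is at distance 0
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t >= -1e-9)
        if hit.any():
            out[i] = max(t[hit].min(), 0.0)
    return out


def ray_surface_distance(
    mesh: TriangleMesh,
    origins: np.ndarray,
    directions: np.ndarray,
    max_range: float,
    bidirectional: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the first ray-surface intersection along +/-direction.

    Returns ``(distances, censored)``; rays with no hit within ``max_range``
    get distance ``max_range`` and ``censored=True``.
    """
    origins = np.asarray(origins, float).reshape(-1, 3)
    directions = np.asarray(directions, float).reshape(-1, 3)
    lens = np.linalg.norm(directions, axis=1)
    if not np.allclose(lens, 1.0, atol=1e-6):
        raise ValueError("ray directions must be unit vectors")
    tri = mesh.triangles
    d_pos = _ray_hits(origins, directions, tri)
    if bidirectional:
        d_neg = _ray_hits(origins, -directions, tri)
        dist = np.minimum(d_pos, d_neg)
    else:
        dist = d_pos
    censored = ~(dist <= max_range)
    dist = np.where(censored, max_range, dist)
    return dist, censored
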