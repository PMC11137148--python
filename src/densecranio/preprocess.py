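"""Surface cleanup: shrink-wrapping and resolution control.

Skull surfaces extracted from CBCT are high-polygon, uneven, and full of
holes and internal structure.  The cleanup used here projects a simple
half-cylindrical surface onto the skull ("shrink-wrap"), which yields a
single-sheet surface with the wrap's regular connectivity and bridges holes
smoothly, then brings the result to a prescribed resolution with an
incremental isotropic remesher (split long edges, collapse short ones,
tangential smoothing, reprojection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh_core import TriangleMesh, project_points

log = logging.getLogger(__name__)

__all__ = [
    "WrapSurface",
    "make_half_cylinder",
    "shrink_wrap",
    "remesh_isotropic",
]

DEFAULT_TARGET_FACES = 30_000
DEFAULT_WRAP_RES = 200


@dataclass
class WrapSurface:
    """Half-cylindrical grid surface enclosing a target on its frontal side."""

    mesh: TriangleMesh
    res_u: int  # angular samples
    res_v: int  # axial samples


def make_half_cylinder(
    target: TriangleMesh,
    margin: float = 10.0,
    res_u: int = DEFAULT_WRAP_RES,
    res_v: int = DEFAULT_WRAP_RES,
    axis: str = "z",
) -> WrapSurface:
    """Half cylinder around the target, open along the coronal cut plane.

    The cylinder axis runs along the superior-inferior (``z``) extent; the
    semicircle spans the anterior (+y) half.  Radius is the maximal lateral
    half-extent plus ``margin``; the vertices form a regular res_u x res_v
    grid (res_u around the arc, res_v along the axis).
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if res_u < 2 or res_v < 2:
        raise ValueError("resolution must be at least 2x2")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    lat = [i for i in range(3) if i != ax]
    bounds = target.bounds()
    extent = bounds[1] - bounds[0]
    if (extent <= 0).any():
        raise ValueError("degenerate bounding box")
    center = bounds.mean(0)
    radius = float(
        np.linalg.norm(target.vertices[:, lat] - center[lat], axis=1).max() + margin
    )
    lo, hi = bounds[0, ax] - margin, bounds[1, ax] + margin
    theta = np.linspace(-np.pi / 2, np.pi / 2, res_u)  # around +y (anterior)
    h = np.linspace(lo, hi, res_v)
    T, H = np.meshgrid(theta, h, indexing="ij")
    v = np.empty((res_u * res_v, 3))
    v[:, lat[0]] = (center[lat[0]] + radius * np.sin(T)).ravel()
    v[:, lat[1]] = (center[lat[1]] + radius * np.cos(T)).ravel()
    v[:, ax] = H.ravel()
    faces = []
    for i in range(res_u - 1):
        for j in range(res_v - 1):
            a = i * res_v + j
            b = a + res_v
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return WrapSurface(TriangleMesh(v, np.asarray(faces, np.int64)), res_u, res_v)


def shrink_wrap(
    wrap: WrapSurface,
    target: TriangleMesh,
    iterations: int = 10,
    smooth_lambda: float = 0.5,
) -> TriangleMesh:
    """Project the wrap onto the target with interleaved Laplacian smoothing.

    Per iteration every wrap vertex is pulled toward its closest point on
    the target; the displacement field is smoothed over the wrap grid with
    weight ``smooth_lambda`` before being applied.  Projections that clamp
    onto a hole rim of the target are treated as unsupported and receive
    their displacement entirely from neighbors, which is what bridges holes
    smoothly instead of piling vertices on the rim.  The fixed point lies on
    the target surface (no Laplacian shrinkage).  ``iterations=0`` returns
    the wrap unchanged; output keeps the wrap's topology, so wrapped
    surfaces stay in grid correspondence.
    """
    from .registration import _boundary_edge_set, _boundary_hits

    mesh = wrap.mesh
    v = mesh.vertices.copy()
    diag = float(np.linalg.norm(target.bounds()[1] - target.bounds()[0]))
    _, dist, _, _ = project_points(target, v, k=1)
    if (dist[:, 0] > 0.5 * diag).mean() > 0.5:
        raise ValueError(
            "more than half of the wrap vertices are far from the target; "
            "the wrap is mis-posed"
        )
    nbr = _neighbor_lists(mesh)
    boundary = _boundary_edge_set(target)
    prev = np.inf
    for _ in range(iterations):
        pos, dist, fid, bary = project_points(target, v, k=4)
        conf = np.where(_boundary_hits(target, fid[:, 0], bary[:, 0], boundary), 0.0, 1.0)
        d = pos[:, 0] - v
        num = conf[:, None] * d
        den = conf.copy()
        for _ in range(2):
            num = 0.5 * num + 0.5 * _neighbor_mean(num, nbr)
            den = 0.5 * den + 0.5 * _neighbor_mean(den[:, None], nbr).ravel()
        d_smooth = num / np.maximum(den[:, None], 1e-12)
        d_used = np.where(
            (conf > 0)[:, None],
            (1 - smooth_lambda) * d + smooth_lambda * d_smooth,
            d_smooth,
        )
        v = v + d_used
        # redistribute along the surface so vertices do not pile up on
        # convex features (spacing equalization without leaving the target)
        if smooth_lambda > 0:
            for _ in range(2):
                v = _tangential_smooth(v, mesh.faces, lam=smooth_lambda,
                                       fix_boundary=False)
        resid = float((dist[:, 0] * conf).sum() / max(conf.sum(), 1.0))
        if prev - resid < 1e-9 and resid < 1e-6 * diag:
            break
        prev = resid
    if iterations > 0:
        # settle supported vertices exactly onto the target surface
        pos, _, fid, bary = project_points(target, v, k=4)
        conf = ~_boundary_hits(target, fid[:, 0], bary[:, 0], boundary)
        v = np.where(conf[:, None], pos[:, 0], v)
    return TriangleMesh(v, mesh.faces.copy())


def _neighbor_lists(mesh: TriangleMesh) -> list[np.ndarray]:
    nbr: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b in mesh.edges_unique():
        nbr[a].add(int(b))
        nbr[b].add(int(a))
    return [np.fromiter(s, np.int64) if s else np.array([i], np.int64)
            for i, s in enumerate(nbr)]


def _neighbor_mean(v: np.ndarray, nbr: list[np.ndarray]) -> np.ndarray:
    out = np.empty_like(v)
    for i, ids in enumerate(nbr):
        out[i] = v[ids].mean(0)
    return out


# ---------------------------------------------------------------------------
# isotropic remeshing
# ---------------------------------------------------------------------------


def remesh_isotropic(
    mesh: TriangleMesh, target_faces: int, n_rounds: int = 6
) -> TriangleMesh:
    """Incremental isotropic remeshing to approximately ``target_faces``.

    Classic split/collapse/smooth/project loop: edges longer than 4/3 of the
    target edge length are split at their midpoint, edges shorter than 4/5
    are collapsed, interior vertices are relaxed tangentially, and everything
    is projected back onto the input surface.  Inputs coarser than the
    target are upsampled by midpoint subdivision first.  Boundary vertices
    are kept fixed so open rims survive.
    """
    if target_faces < 100:
        raise ValueError("target_faces must be >= 100")
    import trimesh as _tm

    v, f = mesh.vertices.copy(), mesh.faces.copy()
    while len(f) < target_faces:
        v, f = _tm.remesh.subdivide(v, f)
    reference = mesh if mesh.n_faces >= 4 else TriangleMesh(v, f)
    area = mesh.area()
    L = float(np.sqrt(4.0 * area / (np.sqrt(3.0) * target_faces)))
    for rnd in range(n_rounds):
        v, f = _split_long_edges(v, f, 4.0 / 3.0 * L)
        v, f = _collapse_short_edges(v, f, 4.0 / 5.0 * L)
        v = _tangential_smooth(v, f)
        pos, _, _, _ = project_points(reference, v, k=4)
        boundary = _boundary_vertices(f, len(v))
        inner = ~boundary
        v[inner] = pos[inner, 0]
        # steer the target edge length toward the requested face budget
        if rnd >= 2:
            ratio = len(f) / target_faces
            if 0.92 < ratio < 1.08:
                break
            L *= np.sqrt(ratio)
    return TriangleMesh(v, f)


def _boundary_vertices(f: np.ndarray, n: int) -> np.ndarray:
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    out = np.zeros(n, bool)
    out[uniq[counts == 1].ravel()] = True
    return out


def _split_long_edges(v: np.ndarray, f: np.ndarray, max_len: float):
    el = np.linalg.norm(v[f[:, [1, 2, 0]]] - v[f], axis=2)  # edges (0-1,1-2,2-0)
    long_mask = el > max_len
    if not long_mask.any():
        return v, f
    mid: dict[tuple[int, int], int] = {}
    newv = [v]
    nv = len(v)

    def midpoint(a: int, b: int) -> int:
        nonlocal nv
        key = (a, b) if a < b else (b, a)
        if key not in mid:
            newv.append(((v[a] + v[b]) / 2)[None])
            mid[key] = nv
            nv += 1
        return mid[key]

    newf = []
    for fi, tri in enumerate(f):
        splits = [c for c in range(3) if long_mask[fi, c]]
        a, b, c = (int(x) for x in tri)
        if not splits:
            newf.append([a, b, c])
        elif len(splits) == 3:
            mab, mbc, mca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            newf += [[a, mab, mca], [mab, b, mbc], [mca, mbc, c], [mab, mbc, mca]]
        elif len(splits) == 1:
            # rotate so the split edge is (a, b)
            for _ in range(splits[0]):
                a, b, c = b, c, a
            m = midpoint(a, b)
            newf += [[a, m, c], [m, b, c]]
        else:  # two split edges; rotate so the un-split edge is (a, b)
            unsplit = ({0, 1, 2} - set(splits)).pop()
            for _ in range(unsplit):
                a, b, c = b, c, a
            mbc, mca = midpoint(b, c), midpoint(c, a)
            newf += [[a, b, mbc], [a, mbc, mca], [mca, mbc, c]]
    return np.vstack(newv), np.asarray(newf, np.int64)


def _collapse_short_edges(v: np.ndarray, f: np.ndarray, min_len: float):
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    e = np.unique(e, axis=0)
    lens = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    order = np.argsort(lens)
    boundary = _boundary_vertices(f, len(v))
    nbr: list[set[int]] = [set() for _ in range(len(v))]
    for a, b in e:
        nbr[a].add(int(b))
        nbr[b].add(int(a))
    parent = np.arange(len(v))
    used = np.zeros(len(v), bool)
    vv = v.copy()
    for idx in order:
        if lens[idx] >= min_len:
            break
        a, b = int(e[idx, 0]), int(e[idx, 1])
        if used[a] or used[b] or boundary[a] or boundary[b]:
            continue
        # link condition: exactly the two opposite vertices in common
        if len(nbr[a] & nbr[b]) > 2:
            continue
        vv[a] = (vv[a] + vv[b]) / 2
        parent[b] = a
        used[a] = used[b] = True
    ff = parent[f]
    keep = (
        (ff[:, 0] != ff[:, 1]) & (ff[:, 1] != ff[:, 2]) & (ff[:, 0] != ff[:, 2])
    )
    ff = ff[keep]
    # compact vertex array
    present = np.unique(ff)
    remap = -np.ones(len(vv), np.int64)
    remap[present] = np.arange(len(present))
    return vv[present], remap[ff]


def _tangential_smooth(
    v: np.ndarray, f: np.ndarray, lam: float = 0.5, fix_boundary: bool = True
) -> np.ndarray:
    mesh = TriangleMesh(v.copy(), f.copy())
    from .mesh_core import vertex_normals

    nrm = vertex_normals(mesh)
    nbr = _neighbor_lists(mesh)
    mean_nb = _neighbor_mean(mesh.vertices, nbr)
    d = mean_nb - mesh.vertices
    d -= np.einsum("ij,ij->i", d, nrm)[:, None] * nrm  # tangential component
    if fix_boundary:
        boundary = _boundary_vertices(mesh.faces, mesh.n_vertices)
        d[boundary] = 0.0
    return mesh.vertices + lam * d
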