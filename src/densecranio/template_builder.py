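"""Construction of the average symmetric template mask.

A set of targets is masked with a preliminary template, the resulting dense
correspondences are averaged by generalized Procrustes analysis, and the
consensus is symmetrized by averaging with its mirror image so the final
template carries no individual asymmetry.  Mirror-pair identification between
left and right quasi-landmarks is done once per template by mutual nearest
neighbors under x-negation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import LandmarkConfiguration, MaskedShape, TriangleMesh
from .registration import NonRigidConfig, register_mask

log = logging.getLogger(__name__)

__all__ = [
    "gpa",
    "centroid_size",
    "plane_symmetrize",
    "mirror_pairing",
    "reflection_average",
    "build_template",
]


def centroid_size(points: np.ndarray) -> float:
    """sqrt of summed squared distances from the centroid (mm)."""
    points = np.asarray(points, float).reshape(-1, 3)
    return float(np.sqrt(((points - points.mean(0)) ** 2).sum()))


def _procrustes_rotation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Proper rotation best mapping centered x onto centered y."""
    U, _, Vt = np.linalg.svd(y.T @ x)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def gpa(
    shapes: Sequence[MaskedShape] | Sequence[np.ndarray],
    with_scaling: bool = True,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generalized Procrustes analysis.

    Centers each shape, optionally scales to unit centroid size, and
    iteratively rotates all shapes to the running consensus until the mean
    changes by less than ``tol``.  Returns ``(mean_shape (Q,3), aligned
    (n,Q,3), centroid_sizes (n,))`` with centroid sizes on the original
    scale.
    """
    arrs = [s.quasi if isinstance(s, MaskedShape) else np.asarray(s, float) for s in shapes]
    if len(arrs) < 2:
        raise ValueError("GPA needs at least 2 shapes")
    Q = arrs[0].shape[0]
    if any(a.shape != (Q, 3) for a in arrs):
        raise ValueError("all shapes must share the same number of quasi-landmarks")
    sizes = np.array([centroid_size(a) for a in arrs])
    X = np.stack([a - a.mean(0) for a in arrs])
    if with_scaling:
        X = X / sizes[:, None, None]
    mean = X[0].copy()
    for _ in range(max_iter):
        for i in range(len(X)):
            R = _procrustes_rotation(X[i], mean)
            X[i] = X[i] @ R.T
        new_mean = X.mean(0)
        if with_scaling:
            new_mean /= np.linalg.norm(new_mean)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    return mean, X, sizes


def plane_symmetrize(mesh: TriangleMesh, axis: str = "x", tol: float = 0.5) -> TriangleMesh:
    """Symmetrize a roughly bilateral mesh about the midsagittal plane.

    Vertices with |x| < ``tol`` are snapped to x = 0, the x >= 0 half is
    kept, and the kept half is mirrored; the output vertex set is exactly
    invariant under reflection.
    """
    if axis != "x":
        raise ValueError("only the x (midsagittal) axis is supported")
    v = mesh.vertices.copy()
    near = np.abs(v[:, 0]) < tol
    if not near.any():
        log.warning("no vertices within %.3g mm of the midplane; seam will be open", tol)
    v[near, 0] = 0.0
    keep_v = v[:, 0] >= 0.0
    # keep faces whose vertices all survive
    keep_f = keep_v[mesh.faces].all(axis=1)
    old2new = -np.ones(len(v), np.int64)
    old2new[keep_v] = np.arange(keep_v.sum())
    half_v = v[keep_v]
    half_f = old2new[mesh.faces[keep_f]]
    # mirror copy: midline vertices (x == 0) are shared, others duplicated
    on_mid = half_v[:, 0] == 0.0
    n_half = len(half_v)
    mirror_idx = np.arange(n_half)
    extra = ~on_mid
    mirror_idx[extra] = n_half + np.arange(extra.sum())
    mirrored_v = half_v[extra] * np.array([-1.0, 1.0, 1.0])
    out_v = np.vstack([half_v, mirrored_v])
    mf = mirror_idx[half_f][:, ::-1]  # flip winding to keep orientation
    out_f = np.vstack([half_f, mf])
    return TriangleMesh(out_v, out_f)


def mirror_pairing(points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Mirror-pair map by mutual nearest neighbor under x-negation.

    Returns an involution ``pair`` with ``pair[pair[i]] == i``; vertices
    without a mutual match within geometric plausibility are self-paired
    (midline).  Exact on meshes produced by :func:`plane_symmetrize`.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    refl = points * np.array([-1.0, 1.0, 1.0])
    tree = cKDTree(points)
    d, j = tree.query(refl)  # j[i]: nearest original to reflection of i
    pair = np.arange(len(points))
    mutual = j[j] == np.arange(len(points))
    pair[mutual] = j[mutual]
    # a "pair" whose partner is itself but sits off-midline is just unmatched
    return pair


def reflection_average(shape: MaskedShape, pairing: np.ndarray) -> MaskedShape:
    """Symmetrize a shape by averaging it with its re-indexed reflection.

    The reflection is re-indexed by the mirror ``pairing`` (an involution),
    aligned back to the original by orthogonal Procrustes (translation +
    rotation), and averaged.  The output is exactly symmetric under
    (reflect + pairing) up to that alignment.
    """
    pairing = np.asarray(pairing, np.int64)
    if not np.array_equal(pairing[pairing], np.arange(len(pairing))):
        raise ValueError("pairing must be an involution")
    x = shape.quasi
    refl = (x * np.array([-1.0, 1.0, 1.0]))[pairing]
    mx, mr = x.mean(0), refl.mean(0)
    R = _procrustes_rotation(refl - mr, x - mx)
    refl_aligned = (refl - mr) @ R.T + mx
    return MaskedShape(0.5 * (x + refl_aligned), shape.template_faces.copy())


def asymmetry_score(shape: MaskedShape, pairing: np.ndarray) -> float:
    """Residual Frobenius distance between a shape and its aligned reflection."""
    x = shape.quasi
    refl = (x * np.array([-1.0, 1.0, 1.0]))[np.asarray(pairing, np.int64)]
    mx, mr = x.mean(0), refl.mean(0)
    R = _procrustes_rotation(refl - mr, x - mx)
    return float(np.linalg.norm((refl - mr) @ R.T + mx - x))


def build_template(
    targets: Sequence[TriangleMesh],
    preliminary_mask: TriangleMesh,
    init_landmarks: Sequence[LandmarkConfiguration],
    mask_landmarks: LandmarkConfiguration,
    cfg: NonRigidConfig | None = None,
) -> TriangleMesh:
    """Average symmetric template from registered targets.

    Registers the preliminary mask to every target, runs GPA with scaling,
    rescales the consensus to the mean original centroid size (so the
    template keeps mm units), and symmetrizes it by reflection averaging.
    The output carries the preliminary mask's topology.
    """
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    if len(init_landmarks) != len(targets):
        raise ValueError("one initialization landmark set per target required")
    masked: list[MaskedShape] = []
    for i, (tgt, lms) in enumerate(zip(targets, init_landmarks)):
        try:
            ms, _ = register_mask(preliminary_mask, tgt, mask_landmarks, lms, cfg)
        except Exception as exc:
            raise RuntimeError(f"registration failed for target {i}: {exc}") from exc
        masked.append(ms)
    mean, _, sizes = gpa(masked, with_scaling=True)
    consensus = mean * (sizes.mean() / centroid_size(mean))
    shape = MaskedShape(consensus, preliminary_mask.faces.copy())
    pairing = mirror_pairing(shape.quasi, tol=1e-3)
    sym = reflection_average(shape, pairing)
    return TriangleMesh(sym.quasi, preliminary_mask.faces.copy())
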