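"""Template-to-target alignment: the three-step masking process.

A template mask is brought into dense correspondence with a target skull
surface by (1) a similarity transform estimated from sparse named landmarks,
(2) rigid/similarity ICP refinement with trimmed correspondences, and (3) an
annealed non-rigid adaptation that moves each template vertex toward the
target surface while smoothing the displacement field over the template
graph.  Step (3) turns the template's vertices into quasi-landmarks: the same
vertex index lands on the same anatomical location of every target.

The non-rigid step is a smoothed-displacement ICP: per iteration it builds
weighted closest-point correspondences, down-weights outliers by a robust MAD
rule (tolerating holes and posterior truncation typical of CBCT scans), and
diffuses the displacement field over the mesh graph with a neighborhood size
("stiffness") annealed from coarse to fine.  Scale is solved during
initialization and rigid ICP, then frozen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .mesh_core import (
    LandmarkConfiguration,
    MaskedShape,
    TriangleMesh,
    project_points,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimilarityTransform",
    "NonRigidConfig",
    "similarity_from_landmarks",
    "rigid_icp",
    "nonrigid_register",
    "register_mask",
    "qc_overlay",
]


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper orthonormal (det +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(pts, float) @ self.rotation.T) + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other (apply ``other`` first)."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * (self.rotation @ other.translation) + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        rt = self.rotation.T
        return SimilarityTransform(rt, -(rt @ self.translation) / self.scale, 1.0 / self.scale)


@dataclass
class NonRigidConfig:
    """Settings of the annealed non-rigid adaptation.

    ``stiffness_start``/``stiffness_end`` are graph-diffusion neighborhood
    sizes (number of smoothing passes); annealed geometrically across
    iterations and required to decrease.  ``inlier_kappa`` is the MAD
    multiplier beyond which correspondences are treated as outliers.
    """

    num_iterations: int = 80
    stiffness_start: float = 40.0
    stiffness_end: float = 4.0
    correspondence_k: int = 3
    inlier_kappa: float = 3.0
    use_symmetric_correspondences: bool = True
    trim_fraction: float = 0.0  # optional hard trim of worst residuals

    def __post_init__(self) -> None:
        if self.num_iterations < 1:
            raise ValueError("num_iterations must be >= 1")
        if self.stiffness_end > self.stiffness_start:
            raise ValueError("stiffness must decrease across iterations")

    def stiffness_schedule(self) -> np.ndarray:
        n = self.num_iterations
        if n == 1:
            return np.array([self.stiffness_start])
        # geometric annealing, coarse-to-fine
        return self.stiffness_start * (self.stiffness_end / self.stiffness_start) ** (
            np.arange(n) / (n - 1)
        )


# ---------------------------------------------------------------------------
# step 1: similarity from sparse landmarks
# ---------------------------------------------------------------------------


def similarity_from_landmarks(
    source: LandmarkConfiguration, target: LandmarkConfiguration
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity transform mapping source landmarks to target.

    Umeyama's closed-form solution minimizing sum ||s R x_i + t - y_i||^2.
    Returns the transform and the residual RMS (mm).
    """
    missing = set(source.names) ^ set(target.names)
    if missing:
        raise ValueError(f"landmark name mismatch: {sorted(missing)}")
    y = target.subset(source.names).points
    x = source.points
    K = len(x)
    if K < 3:
        raise ValueError("need at least 3 landmarks")
    mx, my = x.mean(0), y.mean(0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / K
    if np.linalg.matrix_rank(xc, tol=1e-9 * max(1.0, np.abs(xc).max())) < 2:
        raise ValueError("landmarks are collinear; similarity transform is ill-posed")
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_x = (xc**2).sum() / K
    s = float(np.trace(np.diag(S) @ D) / var_x)
    if s <= 0:
        raise ValueError("degenerate landmark configuration (non-positive scale)")
    t = my - s * (R @ mx)
    tf = SimilarityTransform(R, t, s)
    rms = float(np.sqrt(((tf.apply(x) - y) ** 2).sum(1).mean()))
    return tf, rms


# ---------------------------------------------------------------------------
# step 2: rigid (similarity) ICP
# ---------------------------------------------------------------------------


def _rodrigues(omega: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(omega)
    if theta < 1e-14:
        return np.eye(3)
    k = omega / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _point_to_plane_step(
    x: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    with_scaling: bool,
    weights: np.ndarray | None = None,
) -> SimilarityTransform:
    """Linearized similarity update minimizing sum w ((x' - y) . n)^2."""
    cols = [np.cross(x, n), n]
    if with_scaling:
        cols.append(np.einsum("ij,ij->i", x, n)[:, None])
    A = np.hstack([cols[0], cols[1]] + ([cols[2]] if with_scaling else []))
    b = np.einsum("ij,ij->i", y - x, n)
    if weights is not None:
        sw = np.sqrt(weights)[:, None]
        A = A * sw
        b = b * sw.ravel()
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = sol[:3], sol[3:6]
    sigma = sol[6] if with_scaling else 0.0
    R = _rodrigues(omega)
    return SimilarityTransform(R, t, max(1.0 + sigma, 1e-6))


def rigid_icp(
    mask: TriangleMesh,
    target: TriangleMesh,
    init: SimilarityTransform | None = None,
    max_iter: int = 60,
    trim_fraction: float = 0.2,
    with_scaling: bool = True,
    tol: float = 1e-9,
    anchors: tuple[np.ndarray, np.ndarray] | None = None,
    anchor_weight: float = 0.5,
) -> tuple[SimilarityTransform, float]:
    """ICP with closest-point correspondences and trimmed similarity update.

    Correspondences are exactish surface projections; the transform update is
    a linearized point-to-plane similarity step (fast rotational convergence
    on smooth surfaces) with a point-to-point Umeyama fallback whenever the
    plane step does not improve the objective.  The worst ``trim_fraction``
    of correspondences by residual are excluded every iteration, tolerating
    partial targets (CBCT field-of-view cuts).

    ``anchors=(src_pts, tgt_pts)`` adds soft point-to-point landmark
    constraints carrying ``anchor_weight`` of the total weight: surface
    closest-point terms are blind to tangential sliding on smooth regions,
    and the sparse initialization landmarks are what pins that mode down.
    Stops when the objective improves by less than ``tol`` relatively.
    Returns (transform, final trimmed mean point distance).
    """
    tf = init or SimilarityTransform.identity()
    x0 = mask.vertices
    fn = target.face_normals()
    boundary = _boundary_edge_set(target)
    if anchors is not None:
        a_src = np.asarray(anchors[0], float).reshape(-1, 3)
        a_tgt = np.asarray(anchors[1], float).reshape(-1, 3)
        eye = np.tile(np.eye(3), (len(a_src), 1))

    def correspond(transform):
        x = transform.apply(x0)
        pos, dist, fid, bary = project_points(target, x, k=4)
        y, d = pos[:, 0], dist[:, 0]
        # projections clamped to a hole/truncation rim carry no information
        valid = ~_boundary_hits(target, fid[:, 0], bary[:, 0], boundary)
        d_rank = np.where(valid, d, np.inf)
        n_valid = int(valid.sum())
        n_keep = max(3, min(n_valid, int(np.ceil(len(d) * (1 - trim_fraction)))))
        keep = np.argsort(d_rank)[:n_keep]
        sq = (d[keep] ** 2).sum()
        wsum = float(n_keep)
        if anchors is not None:
            ra = transform.apply(a_src) - a_tgt
            w_a = anchor_weight * n_keep / max(len(a_src), 1)
            sq += w_a * (ra**2).sum()
            wsum += w_a * len(a_src)
        obj = float(np.sqrt(sq / wsum))
        return x, y, d, fn[fid[:, 0]], keep, obj

    x, y, d, nrm, keep, obj = correspond(tf)
    prev = obj
    for it in range(max_iter):
        if obj < 1e-12:
            break
        xs, ys, ns = x[keep], y[keep], nrm[keep]
        ws = np.ones(len(keep))
        if anchors is not None:
            xa = tf.apply(a_src)
            ya = a_tgt
            w_a = anchor_weight * len(keep) / max(len(a_src), 1)
            xs = np.vstack([xs, np.repeat(xa, 3, axis=0)])
            ys = np.vstack([ys, np.repeat(ya, 3, axis=0)])
            ns = np.vstack([ns, eye])
            ws = np.concatenate([ws, np.full(3 * len(a_src), w_a)])
        step = _point_to_plane_step(xs, ys, ns, with_scaling, ws)
        cand = step.compose(tf)
        xc, yc, dc, nc, kc, oc = correspond(cand)
        if oc > obj:
            # fall back to the point-to-point update on the same matches
            src_pts = [x0[keep]]
            dst_pts = [y[keep]]
            if anchors is not None:
                reps = max(1, int(round(w_a)))
                src_pts += [a_src] * reps
                dst_pts += [a_tgt] * reps
            sp = np.vstack(src_pts)
            dp = np.vstack(dst_pts)
            names = [str(i) for i in range(len(sp))]
            step2, _ = similarity_from_landmarks(
                LandmarkConfiguration(names, sp, "m"),
                LandmarkConfiguration(names, dp, "t"),
            )
            if not with_scaling:
                step2 = SimilarityTransform(step2.rotation, step2.translation, 1.0)
            cand = step2
            xc, yc, dc, nc, kc, oc = correspond(cand)
        if oc > obj * 1.5 and obj > 1e-6 and it > 2:
            raise RuntimeError(
                f"rigid ICP diverged at iteration {it} (objective {oc:.4g} > {obj:.4g}); "
                "initialization is likely bad"
            )
        if oc <= obj:
            tf, x, y, d, nrm, keep, obj = cand, xc, yc, dc, nc, kc, oc
        if prev - obj < tol * max(prev, 1e-12):
            break
        prev = obj
    return tf, float(d[keep].mean())


# ---------------------------------------------------------------------------
# step 3: non-rigid adaptation
# ---------------------------------------------------------------------------


def _adjacency(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Row-normalized smoothing operator 0.5*I + 0.5*neighbor-mean."""
    e = mesh.edges_unique()
    n = mesh.n_vertices
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    A = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(1)).ravel()
    deg[deg == 0] = 1.0
    Dinv = sparse.diags(1.0 / deg)
    return (0.5 * sparse.eye(n) + 0.5 * Dinv @ A).tocsr()


def _boundary_edge_set(mesh: TriangleMesh) -> set[tuple[int, int]]:
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return {tuple(edge) for edge in uniq[counts == 1]}


def _boundary_hits(
    target: TriangleMesh,
    fid: np.ndarray,
    bary: np.ndarray,
    boundary: set[tuple[int, int]],
    tol: float = 1e-6,
) -> np.ndarray:
    """True where a projected point lies on a boundary edge of the target.

    Such correspondences come from regions the target does not cover (holes,
    field-of-view truncation): the projection clamps to the rim.
    """
    if not boundary:
        return np.zeros(len(fid), bool)
    out = np.zeros(len(fid), bool)
    faces = target.faces[fid]
    for corner in range(3):
        on_edge = bary[:, corner] < tol  # closest point on the opposite edge
        if not on_edge.any():
            continue
        a = faces[:, (corner + 1) % 3]
        b = faces[:, (corner + 2) % 3]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        for i in np.flatnonzero(on_edge):
            if (int(lo[i]), int(hi[i])) in boundary:
                out[i] = True
    return out


def _correspondence_field(
    x: np.ndarray,
    target: TriangleMesh,
    cfg: NonRigidConfig,
    boundary: set[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted closest-point targets and confidence weights for each vertex."""
    k = max(1, cfg.correspondence_k)
    pos, dist, fid, bary = project_points(target, x, k=k)
    w = 1.0 / (dist + 1e-9)
    w /= w.sum(1, keepdims=True)
    y = np.einsum("nk,nkj->nj", w, pos)
    r = np.linalg.norm(y - x, axis=1)

    # invalid: projection clamped to a hole/truncation rim of the target
    conf = np.where(_boundary_hits(target, fid[:, 0], bary[:, 0], boundary), 0.0, 1.0)
    # robust guard against gross outliers; the MAD floor keeps regions with
    # large genuine deformation from being starved of correspondences
    med = np.median(r)
    mad = np.median(np.abs(r - med)) * 1.4826
    cutoff = med + cfg.inlier_kappa * max(mad, 0.5 * med, 1e-9)
    soft = np.where(r <= cutoff, 1.0, np.exp(-((r - cutoff) / max(cutoff, 1e-9)) ** 2))
    conf *= soft
    n_trim = int(len(r) * cfg.trim_fraction)
    if n_trim > 0:
        conf[np.argsort(r)[-n_trim:]] *= 0.0
    return y, conf


def nonrigid_register(
    mask: TriangleMesh,
    target: TriangleMesh,
    cfg: NonRigidConfig | None = None,
) -> MaskedShape:
    """Adapt the (rigidly pre-aligned) mask shape onto the target surface.

    Per iteration: weighted closest-point correspondences, robust outlier
    down-weighting, and confidence-normalized diffusion of the displacement
    field over the mask graph with the current annealed stiffness.  Output
    preserves the mask topology and vertex count exactly.
    """
    cfg = cfg or NonRigidConfig()
    A = _adjacency(mask)
    x = mask.vertices.copy()
    schedule = cfg.stiffness_schedule()
    boundary = _boundary_edge_set(target)
    for it, stiff in enumerate(schedule):
        y, conf = _correspondence_field(x, target, cfg, boundary)
        d = y - x
        if cfg.use_symmetric_correspondences:
            # pull term: every target vertex attracts its nearest mask vertex,
            # so thin structures are not skipped over
            from scipy.spatial import cKDTree

            xkd = cKDTree(x)
            _, nearest_mask = xkd.query(target.vertices)
            pull = np.zeros_like(x)
            cnt = np.zeros(len(x))
            np.add.at(pull, nearest_mask, target.vertices - x[nearest_mask])
            np.add.at(cnt, nearest_mask, 1.0)
            has = cnt > 0
            pull[has] /= cnt[has, None]
            d = np.where(has[:, None], 0.5 * d + 0.5 * pull, d)
        # confidence-normalized diffusion: conf ~ 0 regions inherit their
        # displacement from reliable neighbors (bridges holes smoothly)
        n_smooth = max(1, int(round(stiff)))
        num = conf[:, None] * d
        den = conf.copy()
        for _ in range(n_smooth):
            num = A @ num
            den = A @ den
        smooth_d = num / np.maximum(den[:, None], 1e-12)
        smooth_d[den < 1e-12] = 0.0
        if not np.isfinite(smooth_d).all():
            raise RuntimeError(f"non-finite displacement at iteration {it}")
        x = x + smooth_d
    return MaskedShape(x, mask.faces.copy())


def register_mask(
    mask: TriangleMesh,
    target: TriangleMesh,
    mask_landmarks: LandmarkConfiguration,
    target_landmarks: LandmarkConfiguration,
    cfg: NonRigidConfig | None = None,
    icp_max_iter: int = 30,
) -> tuple[MaskedShape, SimilarityTransform]:
    """Full 3-step masking: landmark initialization, rigid ICP, non-rigid.

    Returns the masked shape (in target space) and the similarity transform
    found by steps 1-2.
    """
    init, _ = similarity_from_landmarks(mask_landmarks, target_landmarks)
    anchors = (mask_landmarks.points,
               target_landmarks.subset(mask_landmarks.names).points)
    tf, _ = rigid_icp(mask, target, init, max_iter=icp_max_iter, anchors=anchors)
    aligned = mask.transformed(tf.apply)
    masked = nonrigid_register(aligned, target, cfg)
    return masked, tf


# ---------------------------------------------------------------------------
# quality-control overlay
# ---------------------------------------------------------------------------


def qc_overlay(
    masked: MaskedShape, target: TriangleMesh, out_image_path: str | Path
) -> dict:
    """Render front/side overlay views plus a mask-to-target distance histogram.

    Writes a PNG and a JSON with distance statistics alongside; falls back to
    the JSON alone if rendering is unavailable.  Deterministic given inputs.
    """
    out_image_path = Path(out_image_path)
    _, dist, _, _ = project_points(target, masked.quasi, k=4)
    d = dist[:, 0]
    stats = {
        "mean_mm": float(d.mean()),
        "median_mm": float(np.median(d)),
        "p95_mm": float(np.quantile(d, 0.95)),
        "max_mm": float(d.max()),
        "n_quasi": int(len(d)),
    }
    json_path = out_image_path.with_suffix(".json")
    json_path.write_text(json.dumps(stats, indent=1))
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        views = [("front (x-z)", 0, 2), ("side (y-z)", 1, 2)]
        for ax, (title, i, j) in zip(axes[:2], views):
            ax.scatter(target.vertices[:, i], target.vertices[:, j], s=1,
                       c="lightgray", label="target")
            ax.scatter(masked.quasi[:, i], masked.quasi[:, j], s=1, c="crimson",
                       alpha=0.6, label="mask")
            ax.set_title(title)
            ax.set_aspect("equal")
            ax.legend(markerscale=6, fontsize=8)
        axes[2].hist(d, bins=40, color="steelblue")
        axes[2].set_xlabel("mask-to-target distance (mm)")
        axes[2].set_title(f"mean {stats['mean_mm']:.3f} mm")
        fig.tight_layout()
        fig.savefig(out_image_path, dpi=110)
        plt.close(fig)
    except Exception as exc:  # noqa: BLE001 - headless fallback is the contract
        log.warning("QC rendering unavailable (%s); wrote histogram data only", exc)
    return stats
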