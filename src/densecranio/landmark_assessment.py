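"""Classification of quasi-landmarks as "true" (on bone) vs "gap".

Shrink-wrapping bridges orbits, the nasal aperture and regions cut off by
the CBCT field of view, so some template vertices do not correspond to bone.
For each masked skull the distance from every quasi-landmark to the original
(pre-wrap) surface is measured along the vertex normal; a quasi-landmark
whose distance exceeds a threshold (default 10 mm) in more than half of the
skulls is flagged as a gap, and the flags are symmetrized so the same
landmarks are kept on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mesh_core import MaskedShape, TriangleMesh, ray_surface_distance, vertex_normals

__all__ = [
    "TrueLandmarkMask",
    "normal_distance",
    "flag_true_landmarks",
    "topology_fidelity",
    "write_gap_ids",
]

DEFAULT_THRESHOLD_MM = 10.0
DEFAULT_MAX_RANGE_MM = 50.0


@dataclass
class TrueLandmarkMask:
    """Per-quasi-landmark solid/gap flags with supporting exceed counts."""

    flags: np.ndarray  # True = solid ("true") landmark
    exceed_counts: np.ndarray
    n_skulls: int

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, bool)
        self.exceed_counts = np.asarray(self.exceed_counts, np.int64)
        if ((self.exceed_counts < 0) | (self.exceed_counts > self.n_skulls)).any():
            raise ValueError("exceed counts must lie in [0, n_skulls]")

    @property
    def n_true(self) -> int:
        return int(self.flags.sum())

    @property
    def n_gap(self) -> int:
        return int((~self.flags).sum())


def normal_distance(
    masked: MaskedShape,
    original: TriangleMesh,
    normals: np.ndarray | None = None,
    max_range: float = DEFAULT_MAX_RANGE_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each quasi-landmark to the original surface along +/-normal.

    Rays are cast in both normal directions and the nearer hit is taken (the
    wrapped surface can sit inside or outside local bone).  Quasi-landmarks
    with no intersection within ``max_range`` get that value and a censored
    flag.  Returns ``(distances (Q,), censored (Q,))`` in mm.
    """
    if normals is None:
        normals = vertex_normals(masked.as_mesh())
    normals = np.asarray(normals, float).reshape(-1, 3)
    lens = np.linalg.norm(normals, axis=1)
    nonzero = lens > 1e-12
    if not np.allclose(lens[nonzero], 1.0, atol=1e-6):
        raise ValueError("normals must be unit length")
    dist = np.full(masked.n_quasi, max_range)
    cens = np.ones(masked.n_quasi, bool)
    if nonzero.any():
        d, c = ray_surface_distance(
            original, masked.quasi[nonzero], normals[nonzero], max_range,
            bidirectional=True,
        )
        dist[nonzero] = d
        cens[nonzero] = c
    return dist, cens


def flag_true_landmarks(
    distances: np.ndarray,
    pairing: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MM,
) -> TrueLandmarkMask:
    """Majority rule over skulls, then conservative left/right symmetrization.

    ``distances`` is a (n_skulls, Q) matrix of normal distances.  A landmark
    is a gap iff its distance exceeds ``threshold`` in more than half of the
    skulls; a mirror pair is kept only if both members are kept.
    """
    distances = np.atleast_2d(np.asarray(distances, float))
    n_skulls, Q = distances.shape
    pairing = np.asarray(pairing, np.int64)
    if len(pairing) != Q or not np.array_equal(pairing[pairing], np.arange(Q)):
        raise ValueError("pairing must be an involution over the Q landmarks")
    counts = (distances > threshold).sum(axis=0)
    flags = ~(counts > n_skulls / 2)
    flags = flags & flags[pairing]  # conservative AND across the midline
    return TrueLandmarkMask(flags, counts, n_skulls)


def topology_fidelity(
    masked: MaskedShape,
    original: TriangleMesh,
    true_flags: np.ndarray | None = None,
    max_range: float = DEFAULT_MAX_RANGE_MM,
) -> tuple[float, float, np.ndarray]:
    """Mean +/- sd normal distance between mask and original, true landmarks only.

    Returns ``(mean, sd, per-vertex distances over the true set)``.
    """
    dist, _ = normal_distance(masked, original, max_range=max_range)
    if true_flags is not None:
        true_flags = np.asarray(true_flags, bool)
        dist = dist[true_flags]
    if len(dist) == 0:
        raise ValueError("empty true-landmark set")
    return float(dist.mean()), float(dist.std()), dist


def write_gap_ids(mask: TrueLandmarkMask, path: str | Path) -> Path:
    """Write 0-based vertex IDs of gap landmarks, one per line."""
    path = Path(path)
    ids = np.flatnonzero(~mask.flags)
    path.write_text("\n".join(str(i) for i in ids) + ("\n" if len(ids) else ""))
    return path
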