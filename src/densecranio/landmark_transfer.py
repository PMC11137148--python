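"""Sparse landmark transfer through the dense correspondence.

A manual landmark on a masked skull is encoded as barycentric weights over
its three closest quasi-landmarks.  Because quasi-landmark indices mean the
same anatomical location on every masked individual, the encoding can be
decoded on any other masked skull: each training skull contributes one
anchor, the decoded positions on the target are averaged, and the average is
projected to the closest point on the target's actual surface (the mean of
several decodes need not lie on it).  Leave-one-out orchestration turns this
into an accuracy measurement against held-out manual landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mesh_core import (
    LandmarkConfiguration,
    MaskedShape,
    TriangleMesh,
    closest_surface_points,
)

__all__ = [
    "BarycentricAnchor",
    "encode_barycentric",
    "decode_barycentric",
    "transfer_landmarks",
    "loo_evaluate",
]

_COLLINEAR_COND = 1e8


@dataclass
class BarycentricAnchor:
    """One landmark as affine weights over 3 quasi-landmark indices.

    Weights sum to 1 but may be negative (the landmark can lie outside the
    triangle of its three nearest quasi-landmarks).
    """

    quasi_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.quasi_ids = np.asarray(self.quasi_ids, np.int64).reshape(3)
        self.weights = np.asarray(self.weights, float).reshape(3)
        if len(set(self.quasi_ids.tolist())) != 3:
            raise ValueError("quasi_ids must be distinct")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def encode_barycentric(landmark: np.ndarray, masked: MaskedShape) -> BarycentricAnchor:
    """Encode a point over its 3 nearest quasi-landmarks.

    Weights are the affine (barycentric) coordinates of the landmark's
    orthogonal projection onto the plane of the three points; a collinear
    triple (condition number > 1e8) falls back to normalized inverse-distance
    weights.  Ties in nearest-3 selection break toward the lowest index.
    """
    p = np.asarray(landmark, float).reshape(3)
    if not np.isfinite(p).all():
        raise ValueError("landmark must be finite")
    if masked.n_quasi < 3:
        raise ValueError("need at least 3 quasi-landmarks")
    d = np.linalg.norm(masked.quasi - p, axis=1)
    ids = np.lexsort((np.arange(len(d)), d))[:3]  # stable: lowest index on ties
    ids = np.sort(ids)
    a, b, c = masked.quasi[ids]
    M = np.column_stack([b - a, c - a])
    G = M.T @ M
    cond = np.linalg.cond(G) if np.linalg.det(G) != 0 else np.inf
    if cond > _COLLINEAR_COND:
        dd = np.maximum(d[ids], 1e-12)
        w = 1.0 / dd
        w = w / w.sum()
    else:
        uv = np.linalg.solve(G, M.T @ (p - a))
        w = np.array([1.0 - uv.sum(), uv[0], uv[1]])
    w = w / w.sum()  # guard rounding so the invariant holds exactly
    return BarycentricAnchor(ids, w)


def decode_barycentric(anchor: BarycentricAnchor, masked: MaskedShape) -> np.ndarray:
    """Weighted sum of the anchor's quasi-landmarks on ``masked``."""
    if anchor.quasi_ids.max() >= masked.n_quasi:
        raise IndexError("anchor quasi_id out of range for this masked shape")
    return anchor.weights @ masked.quasi[anchor.quasi_ids]


def transfer_landmarks(
    train: Sequence[tuple[MaskedShape, LandmarkConfiguration]],
    target_masked: MaskedShape,
    target_mesh: TriangleMesh,
) -> LandmarkConfiguration:
    """Transfer named landmarks from training skulls onto a target.

    Per landmark: encode on each training masked shape, decode every anchor
    on the target's masked shape, average the decoded positions, and project
    the average to the closest point on the target surface.
    """
    if not train:
        raise ValueError("need at least one training shape")
    names = list(train[0][1].names)
    for _, lc in train[1:]:
        if set(lc.names) != set(names):
            diff = set(lc.names) ^ set(names)
            raise ValueError(f"training landmark names differ: {sorted(diff)}")
    decoded = np.zeros((len(names), 3))
    for masked, lc in train:
        pts = lc.subset(names).points
        for k, p in enumerate(pts):
            anchor = encode_barycentric(p, masked)
            decoded[k] += decode_barycentric(anchor, target_masked)
    decoded /= len(train)
    projected = closest_surface_points(target_mesh, decoded)
    return LandmarkConfiguration(names, np.array([sp.position for sp in projected]),
                                 frame="target")


def loo_evaluate(
    shapes: Sequence[tuple[MaskedShape, TriangleMesh, Mapping[str, LandmarkConfiguration]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out transfer accuracy against manual landmarks.

    ``shapes[i]`` is (masked, mesh, {observer: manual landmarks}); an
    ``"average"`` entry is added per skull as the observer mean.  For each
    held-out skull, landmarks are transferred from all others (using the same
    observer's manual landmarks on the training skulls) and compared to the
    held-out manual placement.

    Returns ``(long, summary)``: a long table (skull, landmark, observer,
    distance_mm) and per-landmark descriptive statistics (Mean, Std, Min,
    Max over skull x observer) shaped like a per-landmark accuracy table.
    """
    if len(shapes) < 3:
        raise ValueError("leave-one-out needs at least 3 shapes")
    observers = sorted(shapes[0][2].keys())
    names = list(shapes[0][2][observers[0]].names)

    def obs_sets(entry):
        out = dict(entry)
        mean_pts = np.mean([out[o].subset(names).points for o in observers], axis=0)
        out["average"] = LandmarkConfiguration(names, mean_pts, frame="average")
        return out

    enriched = [(m, mesh, obs_sets(lmk)) for m, mesh, lmk in shapes]
    rows = []
    for held in range(len(enriched)):
        target_masked, target_mesh, target_lmk = enriched[held]
        train_entries = [e for i, e in enumerate(enriched) if i != held]
        if len(train_entries) < 2:
            raise ValueError("need at least 2 training shapes")
        for obs in observers + ["average"]:
            train = [(m, lmk[obs]) for m, _, lmk in train_entries]
            auto = transfer_landmarks(train, target_masked, target_mesh)
            manual = target_lmk[obs].subset(names).points
            dist = np.linalg.norm(auto.points - manual, axis=1)
            for k, name in enumerate(names):
                rows.append(
                    {"skull": held, "landmark": name, "observer": obs,
                     "distance_mm": float(dist[k])}
                )
    long = pd.DataFrame(rows)
    avg = long[long["observer"] == "average"]
    summary = (
        avg.groupby("landmark", sort=False)["distance_mm"]
        .agg(Mean="mean", Std="std", Min="min", Max="max")
        .reset_index()
    )
    return long, summary
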