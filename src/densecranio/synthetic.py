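"""Synthetic skull-like fixtures with exact ground truth.

Real craniofacial CBCT cohorts are not publicly shareable, so every stage of
the pipeline is exercised on generated surfaces instead: an ellipsoidal
cranium with nasal / zygomatic / orbital features, per-individual smooth
random deformation fields, optional posterior truncation and holes emulating
limited CBCT field of view, and repeated noisy manual landmarking by
observers of differing skill.

Because each individual is produced by deforming the *same* base mesh, the
ground-truth dense correspondence (a :class:`~densecranio.mesh_core.MaskedShape`)
and the true positions of the 20 named landmarks are known exactly, which is
what lets registration and transfer errors be measured rather than estimated.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec; the same seed yields byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh

from .mesh_core import (
    LandmarkConfiguration,
    MaskedShape,
    TriangleMesh,
    closest_surface_points,
)

__all__ = [
    "SyntheticPopulationSpec",
    "ObserverSpec",
    "Individual",
    "generate_base_skull",
    "generate_population",
    "simulate_observers",
    "initialization_landmarks",
    "template_initialization_landmarks",
]

# 20 validation landmarks: (name, unit direction on the ellipsoid) with
# +x lateral-left, +y anterior, +z superior.  Midline landmarks sit at x=0;
# the rest come in bilateral pairs.
_LANDMARK_DIRECTIONS: list[tuple[str, tuple[float, float, float]]] = [
    ("Nasion", (0.0, 0.95, 0.45)),
    ("Subspinale", (0.0, 1.0, -0.25)),
    ("Incision", (0.0, 0.95, -0.55)),
    ("Pogonion", (0.0, 0.85, -0.85)),
    ("Right Frontomalare Orbital", (-0.55, 0.75, 0.45)),
    ("Left Frontomalare Orbital", (0.55, 0.75, 0.45)),
    ("Right Orbitale", (-0.40, 0.90, 0.05)),
    ("Left Orbitale", (0.40, 0.90, 0.05)),
    ("Right Zygomaxillare", (-0.55, 0.80, -0.15)),
    ("Left Zygomaxillare", (0.55, 0.80, -0.15)),
    ("Right Intercanine", (-0.12, 1.0, -0.50)),
    ("Left Intercanine", (0.12, 1.0, -0.50)),
    ("Right Marginal Tubercle", (-0.75, 0.45, 0.30)),
    ("Left Marginal Tubercle", (0.75, 0.45, 0.30)),
    ("Right Zygion", (-0.95, 0.30, 0.0)),
    ("Left Zygion", (0.95, 0.30, 0.0)),
    ("Right Koronion", (-0.80, 0.35, -0.35)),
    ("Left Koronion", (0.80, 0.35, -0.35)),
    ("Right Gonion", (-0.70, 0.15, -0.70)),
    ("Left Gonion", (0.70, 0.15, -0.70)),
]

VALIDATION_LANDMARK_NAMES = [n for n, _ in _LANDMARK_DIRECTIONS]


@dataclass
class SyntheticPopulationSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate an adult CBCT skull cohort: semi-axes of roughly a human
    cranium (mm), individual smooth shape variation of a few millimetres RMS
    at a ~40 mm spatial wavelength, mild fluctuating asymmetry, and posterior
    truncation mimicking the limited CBCT field of view.
    """

    n_individuals: int = 10
    deformation_amplitude: float = 3.0  # RMS vertex displacement, mm
    deformation_wavelength: float = 40.0  # RBF kernel width, mm
    asymmetry_sd: float = 0.5  # mm
    truncation_fraction: float = 0.0  # posterior fraction of faces removed
    hole_spec: Sequence[tuple[Sequence[float], float]] = ()
    subdivisions: int = 3  # icosphere refinement of the base mesh
    semi_axes: tuple[float, float, float] = (65.0, 85.0, 75.0)
    n_bumps: int = 30  # RBF bumps per deformation field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation_amplitude < 0 or self.asymmetry_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.truncation_fraction < 1:
            raise ValueError("truncation_fraction must be in [0, 1)")


@dataclass
class ObserverSpec:
    """Manual-landmarking noise model.

    Defaults are three observers of decreasing skill landmarking three rounds
    each, with per-round isotropic noise plus a smooth per-observer systematic
    bias field (smooth rather than iid so that inter-observer dispersion
    exceeds intra-observer dispersion, as seen with real observers).
    """

    n_observers: int = 3
    noise_sd: Sequence[float] = (0.3, 0.6, 0.9)  # mm, per observer per round
    bias_amplitude: Sequence[float] = (0.5, 1.0, 1.5)  # mm, per observer
    bias_wavelength: float = 60.0  # mm
    n_rounds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.noise_sd) != self.n_observers or len(self.bias_amplitude) != self.n_observers:
            raise ValueError("noise_sd / bias_amplitude must have one entry per observer")
        if min(self.noise_sd) < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Individual:
    """One synthetic skull with its exact ground truth."""

    mesh: TriangleMesh
    truth_masked: MaskedShape
    truth_landmarks: LandmarkConfiguration


def generate_base_skull(spec: SyntheticPopulationSpec) -> tuple[TriangleMesh, np.ndarray]:
    """Ellipsoid cranium with nasal/zygomatic ridges and orbital depressions.

    Returns the base mesh and the vertex indices of the 20 named landmarks.
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions)
    u = np.asarray(ico.vertices, float)  # unit sphere
    a, b, c = spec.semi_axes
    v = u * np.array([a, b, c])

    # anatomical features as radial Gaussian bumps on the unit sphere
    def bump(center, width, height):
        center = np.asarray(center, float)
        center = center / np.linalg.norm(center)
        d2 = ((u - center) ** 2).sum(1)
        return height * np.exp(-d2 / (2 * width**2))

    radial = np.zeros(len(u))
    radial += bump((0.0, 1.0, -0.1), 0.18, 10.0)    # nasal/maxillary ridge
    radial += bump((-0.8, 0.4, 0.0), 0.18, 9.0)     # right zygomatic arch
    radial += bump((0.8, 0.4, 0.0), 0.18, 9.0)      # left zygomatic arch
    radial -= bump((-0.35, 0.85, 0.25), 0.12, 7.0)  # right orbit
    radial -= bump((0.35, 0.85, 0.25), 0.12, 7.0)   # left orbit
    radial += bump((0.0, 0.8, 0.55), 0.20, 6.0)     # glabella / brow
    radial += bump((0.0, 0.9, -0.6), 0.14, 7.0)     # alveolar / teeth row
    radial += bump((0.0, 0.75, -0.95), 0.15, 8.0)   # chin / mental protuberance
    radial -= bump((0.0, -0.2, -0.9), 0.25, 6.0)    # foramen magnum region
    radial += bump((0.0, -1.0, 0.1), 0.20, 6.0)     # occipital bun
    radial += bump((-0.6, -0.5, 0.6), 0.18, 5.0)    # right parietal boss
    radial += bump((0.6, -0.5, 0.6), 0.18, 5.0)     # left parietal boss
    radial -= bump((-0.95, 0.15, 0.15), 0.13, 5.0)  # right temporal fossa
    radial -= bump((0.95, 0.15, 0.15), 0.13, 5.0)   # left temporal fossa
    v = v + radial[:, None] * u

    base = TriangleMesh(v, np.asarray(ico.faces, np.int64))
    lm_ids = _landmark_vertex_ids(base)
    return base, lm_ids


def _landmark_vertex_ids(base: TriangleMesh) -> np.ndarray:
    dirs = np.array([d for _, d in _LANDMARK_DIRECTIONS], float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radial = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    ids = np.argmax(radial @ dirs.T, axis=0)
    if len(set(ids.tolist())) != len(ids):
        raise RuntimeError("landmark directions collapsed onto one vertex; refine the base mesh")
    return ids.astype(np.int64)


def _rbf_field(
    points: np.ndarray,
    rng: np.random.Generator,
    n_bumps: int,
    wavelength: float,
    rms_amplitude: float,
    centers_on: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth random displacement field with a prescribed RMS magnitude."""
    if rms_amplitude == 0:
        return np.zeros_like(points)
    src = centers_on if centers_on is not None else points
    centers = src[rng.integers(0, len(src), size=n_bumps)]
    dirs = rng.normal(size=(n_bumps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.normal(size=n_bumps)
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2 * wavelength**2)) * amps[None, :]
    disp = w @ dirs
    rms = np.sqrt((disp**2).sum(1).mean())
    if rms < 1e-12:
        return np.zeros_like(points)
    return disp * (rms_amplitude / rms)


def generate_population(spec: SyntheticPopulationSpec) -> tuple[TriangleMesh, list[Individual]]:
    """Generate the cohort; returns (base/template mesh, individuals).

    Each individual's mesh is the base deformed by a smooth random field plus
    an asymmetric perturbation, optionally truncated posteriorly and punched
    with holes; its ``truth_masked`` holds the deformed base vertices (the
    exact dense correspondence) and ``truth_landmarks`` the 20 carried
    landmark positions.
    """
    rng = np.random.default_rng(spec.seed)
    base, lm_ids = generate_base_skull(spec)
    individuals: list[Individual] = []
    for _ in range(spec.n_individuals):
        disp = _rbf_field(
            base.vertices, rng, spec.n_bumps, spec.deformation_wavelength,
            spec.deformation_amplitude,
        )
        if spec.asymmetry_sd > 0:
            asym = _rbf_field(
                base.vertices, rng, max(spec.n_bumps // 3, 1),
                spec.deformation_wavelength, spec.asymmetry_sd,
            )
            disp = disp + asym
        verts = base.vertices + disp
        faces = base.faces.copy()
        faces = _apply_truncation_and_holes(verts, faces, spec)
        _check_landmarks_survive(faces, lm_ids)
        mesh = TriangleMesh(verts.copy(), faces)
        individuals.append(
            Individual(
                mesh=mesh,
                truth_masked=MaskedShape(verts.copy(), base.faces.copy()),
                truth_landmarks=LandmarkConfiguration(
                    VALIDATION_LANDMARK_NAMES, verts[lm_ids].copy(), frame="truth"
                ),
            )
        )
    return base, individuals


def _apply_truncation_and_holes(
    verts: np.ndarray, faces: np.ndarray, spec: SyntheticPopulationSpec
) -> np.ndarray:
    keep = np.ones(len(faces), bool)
    cen = verts[faces].mean(1)
    if spec.truncation_fraction > 0:
        cut = np.quantile(cen[:, 1], spec.truncation_fraction)  # posterior = low y
        keep &= cen[:, 1] >= cut
    for center, radius in spec.hole_spec:
        keep &= np.linalg.norm(cen - np.asarray(center, float), axis=1) > radius
    return faces[keep]


def _check_landmarks_survive(faces: np.ndarray, lm_ids: np.ndarray) -> None:
    present = np.unique(faces)
    missing = [VALIDATION_LANDMARK_NAMES[i] for i, vid in enumerate(lm_ids)
               if vid not in present]
    if missing:
        raise ValueError(
            "truncation/hole removed landmark(s): " + ", ".join(missing)
        )


def initialization_landmarks(
    individual: Individual, base: TriangleMesh, n: int = 11, seed: int = 0
) -> LandmarkConfiguration:
    """Pick ``n`` well-spread registration-initialization landmarks.

    Farthest-point sampling on the base mesh (deterministic given seed),
    carried to the individual through the ground-truth correspondence.  Used
    where a user would click the sparse initialization points.
    """
    rng = np.random.default_rng(seed)
    ids = _farthest_point_ids(base.vertices, n, int(rng.integers(0, len(base.vertices))))
    names = [f"init{i:02d}" for i in range(n)]
    return LandmarkConfiguration(names, individual.truth_masked.quasi[ids], frame="init")


def template_initialization_landmarks(
    base: TriangleMesh, n: int = 11, seed: int = 0
) -> LandmarkConfiguration:
    """The same initialization points expressed on the template itself."""
    rng = np.random.default_rng(seed)
    ids = _farthest_point_ids(base.vertices, n, int(rng.integers(0, len(base.vertices))))
    names = [f"init{i:02d}" for i in range(n)]
    return LandmarkConfiguration(names, base.vertices[ids], frame="template")


def _farthest_point_ids(pts: np.ndarray, n: int, start: int) -> np.ndarray:
    ids = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        ids.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.asarray(ids, np.int64)


def simulate_observers(
    individuals: Sequence[Individual],
    spec: ObserverSpec,
) -> np.ndarray:
    """Simulate repeated manual landmarking.

    Returns a (skull, observer, round, K, 3) array: truth + the observer's
    smooth bias field evaluated at the landmark + isotropic round noise,
    re-projected onto the individual's surface (observers can only click on
    the rendered surface).
    """
    rng = np.random.default_rng(spec.seed)
    K = len(individuals[0].truth_landmarks)
    out = np.empty((len(individuals), spec.n_observers, spec.n_rounds, K, 3))
    # one smooth bias field per observer, shared across skulls (systematic
    # interpretation differences, e.g. where "gonion" is read on a curve)
    all_pts = np.vstack([ind.truth_landmarks.points for ind in individuals])
    bias_fields = []
    for o in range(spec.n_observers):
        field_all = _rbf_field(
            all_pts, rng, 20, spec.bias_wavelength, spec.bias_amplitude[o]
        )
        bias_fields.append(field_all.reshape(len(individuals), K, 3))
    for s, ind in enumerate(individuals):
        for o in range(spec.n_observers):
            for r in range(spec.n_rounds):
                noisy = (
                    ind.truth_landmarks.points
                    + bias_fields[o][s]
                    + rng.normal(scale=spec.noise_sd[o], size=(K, 3))
                )
                if spec.noise_sd[o] > 0 or spec.bias_amplitude[o] > 0:
                    sp = closest_surface_points(ind.mesh, noisy)
                    noisy = np.array([p.position for p in sp])
                out[s, o, r] = noisy
    return out
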