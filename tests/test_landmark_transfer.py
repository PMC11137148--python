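"""Barycentric landmark encoding, decoding, transfer, and leave-one-out."""

import numpy as np
import pytest

from densecranio.mesh_core import LandmarkConfiguration, MaskedShape
from densecranio.landmark_transfer import (
    BarycentricAnchor,
    decode_barycentric,
    encode_barycentric,
    loo_evaluate,
    transfer_landmarks,
)
from densecranio.registration import SimilarityTransform
from densecranio.synthetic import (
    ObserverSpec,
    SyntheticPopulationSpec,
    VALIDATION_LANDMARK_NAMES,
    generate_population,
    simulate_observers,
)


def _masked(base):
    return MaskedShape(base.vertices.copy(), base.faces.copy())


class TestEncodeDecode:
    def test_landmark_at_quasi_vertex(self, base_and_population):
        base, _ = base_and_population
        shape = _masked(base)
        a = encode_barycentric(shape.quasi[17], shape)
        assert 17 in a.quasi_ids
        w = a.weights[list(a.quasi_ids).index(17)]
        assert w == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(decode_barycentric(a, shape), shape.quasi[17],
                                   atol=1e-9)

    def test_centroid_of_nearest_triple(self):
        quasi = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [50, 50, 50.0]])
        shape = MaskedShape(quasi, np.array([[0, 1, 2]]))
        p = quasi[:3].mean(0)
        a = encode_barycentric(p, shape)
        np.testing.assert_allclose(sorted(a.weights), [1 / 3] * 3, atol=1e-9)

    def test_roundtrip_reproduces_in_plane_projection(self, rng, base_and_population):
        base, _ = base_and_population
        shape = _masked(base)
        for _ in range(25):
            p = base.vertices[rng.integers(base.n_vertices)] + rng.normal(scale=2, size=3)
            a = encode_barycentric(p, shape)
            dec = decode_barycentric(a, shape)
            tri = shape.quasi[a.quasi_ids]
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            n = n / np.linalg.norm(n)
            proj = p - np.dot(p - tri[0], n) * n
            np.testing.assert_allclose(dec, proj, atol=1e-9)

    def test_negative_weight_extrapolation(self):
        quasi = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        shape = MaskedShape(quasi, np.array([[0, 1, 2]]))
        a = BarycentricAnchor(np.array([0, 1, 2]), np.array([-1.0, 1.0, 1.0]))
        np.testing.assert_allclose(decode_barycentric(a, shape), [1.0, 1.0, 0.0],
                                   atol=1e-12)

    def test_midpoint_decode(self):
        quasi = np.array([[0, 0, 0], [2, 0, 0], [9, 9, 9.0]])
        shape = MaskedShape(quasi, np.array([[0, 1, 2]]))
        a = BarycentricAnchor([0, 1, 2], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(decode_barycentric(a, shape), [1, 0, 0], atol=1e-12)

    def test_collinear_fallback_weights(self):
        quasi = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [90, 0, 0.0]])
        shape = MaskedShape(quasi, np.array([[0, 1, 2]]))
        a = encode_barycentric(np.array([0.5, 1.0, 0.0]), shape)
        assert a.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (a.weights > 0).all()  # inverse-distance fallback

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BarycentricAnchor([0, 0, 1], [0.5, 0.25, 0.25])  # duplicate ids
        with pytest.raises(ValueError):
            BarycentricAnchor([0, 1, 2], [0.5, 0.25, 0.1])  # sum != 1
        shape = MaskedShape(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(IndexError):
            decode_barycentric(BarycentricAnchor([0, 1, 7], [0.5, 0.25, 0.25]), shape)


class TestTransfer:
    def test_self_transfer_projects_to_own_surface(self, base_and_population):
        base, inds = base_and_population
        ind = inds[0]
        masked = MaskedShape(ind.truth_masked.quasi, base.faces)
        train = [(masked, ind.truth_landmarks)]
        out = transfer_landmarks(train, masked, ind.mesh)
        err = np.linalg.norm(out.points - ind.truth_landmarks.points, axis=1)
        assert err.max() < 1e-6  # truth landmarks lie on the surface

    def test_output_always_on_surface(self, base_and_population, rng):
        base, inds = base_and_population
        masked = [MaskedShape(i.truth_masked.quasi, base.faces) for i in inds]
        train = [(masked[i], inds[i].truth_landmarks) for i in range(4)]
        out = transfer_landmarks(train, masked[4], inds[4].mesh)
        from densecranio.mesh_core import closest_surface_points

        sps = closest_surface_points(inds[4].mesh, out.points)
        d = [np.linalg.norm(sp.position - p) for sp, p in zip(sps, out.points)]
        assert max(d) < 1e-9

    def test_transfer_beats_observer_noise(self):
        # training landmarks corrupted with sigma = 1 mm observer noise:
        # the averaged transfer should err less than that noise
        spec = SyntheticPopulationSpec(n_individuals=11, seed=31)
        base, inds = generate_population(spec)
        rng = np.random.default_rng(32)
        sigma = 1.0
        masked = [MaskedShape(i.truth_masked.quasi, base.faces) for i in inds]
        train = []
        for i in range(10):
            noisy = inds[i].truth_landmarks.points + rng.normal(
                scale=sigma, size=(20, 3)
            )
            train.append(
                (masked[i], LandmarkConfiguration(VALIDATION_LANDMARK_NAMES, noisy))
            )
        out = transfer_landmarks(train, masked[10], inds[10].mesh)
        err = np.linalg.norm(out.points - inds[10].truth_landmarks.points, axis=1)
        assert err.mean() < sigma

    def test_equivariance_under_rigid_motion(self, base_and_population):
        base, inds = base_and_population
        masked = [MaskedShape(i.truth_masked.quasi, base.faces) for i in inds]
        train = [(masked[i], inds[i].truth_landmarks) for i in range(4)]
        out1 = transfer_landmarks(train, masked[4], inds[4].mesh)
        c, s = np.cos(0.6), np.sin(0.6)
        move = SimilarityTransform(
            np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]), [15, 3, -7], 1.0
        )
        moved_masked = MaskedShape(move.apply(masked[4].quasi), base.faces)
        moved_mesh = inds[4].mesh.transformed(move.apply)
        out2 = transfer_landmarks(train, moved_masked, moved_mesh)
        np.testing.assert_allclose(out2.points, move.apply(out1.points), atol=1e-6)

    def test_name_mismatch_rejected(self, base_and_population):
        base, inds = base_and_population
        masked = MaskedShape(inds[0].truth_masked.quasi, base.faces)
        other = LandmarkConfiguration(["weird"], [[0, 0, 0]])
        with pytest.raises(ValueError, match="differ"):
            transfer_landmarks(
                [(masked, inds[0].truth_landmarks), (masked, other)],
                masked, inds[0].mesh,
            )


class TestLeaveOneOut:
    def _shapes(self, base, inds, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        shapes = []
        for ind in inds:
            pts = ind.truth_landmarks.points
            per_obs = {
                "obs1": LandmarkConfiguration(
                    VALIDATION_LANDMARK_NAMES,
                    pts + rng.normal(scale=noise, size=pts.shape) if noise else pts,
                )
            }
            shapes.append(
                (MaskedShape(ind.truth_masked.quasi, base.faces), ind.mesh, per_obs)
            )
        return shapes

    def test_zero_noise_zero_errors(self, base_and_population):
        base, inds = base_and_population
        long, summary = loo_evaluate(self._shapes(base, inds))
        assert (long["distance_mm"] >= 0).all()
        assert long["distance_mm"].max() < 0.05  # identity deformations, truth inputs

    def test_summary_consistent_with_long_table(self, base_and_population):
        base, inds = base_and_population
        long, summary = loo_evaluate(self._shapes(base, inds, noise=0.5, seed=3))
        avg = long[long["observer"] == "average"]
        for _, row in summary.iterrows():
            sel = avg[avg["landmark"] == row["landmark"]]["distance_mm"]
            assert row["Mean"] == pytest.approx(sel.mean())
            assert row["Min"] == pytest.approx(sel.min())
            assert row["Max"] == pytest.approx(sel.max())

    def test_needs_three_shapes(self, base_and_population):
        base, inds = base_and_population
        with pytest.raises(ValueError):
            loo_evaluate(self._shapes(base, inds[:2]))

    def test_error_shrinks_with_training_size(self):
        # iid observer noise: transfer error from 10 training shapes should
        # beat transfer from 2 (averaging over anchors)
        spec = SyntheticPopulationSpec(n_individuals=12, deformation_amplitude=1.0,
                                       seed=40)
        base, inds = generate_population(spec)
        rng = np.random.default_rng(41)
        sigma = 1.5
        masked = [MaskedShape(i.truth_masked.quasi, base.faces) for i in inds]
        noisy = [
            LandmarkConfiguration(
                VALIDATION_LANDMARK_NAMES,
                i.truth_landmarks.points + rng.normal(scale=sigma, size=(20, 3)),
            )
            for i in inds
        ]

        def err(n_train):
            train = [(masked[i], noisy[i]) for i in range(n_train)]
            out = transfer_landmarks(train, masked[11], inds[11].mesh)
            return np.linalg.norm(out.points - inds[11].truth_landmarks.points,
                                  axis=1).mean()

        assert err(10) < err(2)

    def test_sliding_landmarks_err_more_than_point_landmarks(self):
        # anisotropic noise along a contour direction inflates errors for
        # "sliding" landmarks relative to well-defined point landmarks
        spec = SyntheticPopulationSpec(n_individuals=8, seed=50)
        base, inds = generate_population(spec)
        rng = np.random.default_rng(51)
        masked = [MaskedShape(i.truth_masked.quasi, base.faces) for i in inds]
        K = 20
        sliding = np.arange(10)  # first half: noise stretched along +z contour
        shapes = []
        for ind in inds:
            pts = ind.truth_landmarks.points.copy()
            noise = rng.normal(scale=0.2, size=(K, 3))
            noise[sliding, 2] += rng.normal(scale=2.0, size=10)
            shapes.append(
                (
                    MaskedShape(ind.truth_masked.quasi, base.faces), ind.mesh,
                    {"obs1": LandmarkConfiguration(VALIDATION_LANDMARK_NAMES,
                                                   pts + noise)},
                )
            )
        long, _ = loo_evaluate(shapes)
        avg = long[long["observer"] == "average"]
        per_lm = avg.groupby("landmark", sort=False)["distance_mm"].mean()
        slide_err = per_lm.iloc[:10].mean()
        point_err = per_lm.iloc[10:].mean()
        assert slide_err > point_err
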