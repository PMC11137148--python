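"""Reliability / accuracy statistics: RMS, ICC, Bland-Altman, ANOVA, R^2, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from densecranio.morpho_stats import (
    anova_centroid,
    bland_altman,
    icc,
    residualize_covariates,
    rms_between,
    rms_repeat,
    shape_pca,
    shape_variance_decomposition,
)


class TestRmsRepeat:
    def test_identical_rounds_zero(self, rng):
        c = rng.normal(size=(1, 10, 3)).repeat(3, axis=0)
        per, mean = rms_repeat(c)
        assert mean < 1e-12

    def test_two_round_hand_oracle(self):
        # one landmark at (0,0,0) and (1,0,0): each round 0.5 from the mean
        c = np.zeros((2, 1, 3))
        c[1, 0, 0] = 1.0
        per, mean = rms_repeat(c)
        assert per[0] == pytest.approx(0.5, abs=1e-12)

    def test_gaussian_noise_closed_form(self):
        # iid noise sigma per axis: E[RMS^2] = 3 sigma^2 (R-1)/R
        rng = np.random.default_rng(7)
        sigma, R, K = 0.8, 3, 4000
        c = rng.normal(scale=sigma, size=(R, K, 3))
        _, mean = rms_repeat(c)
        expected = sigma * np.sqrt(3) * np.sqrt((R - 1) / R)
        assert mean == pytest.approx(expected, rel=0.05)

    def test_pairwise_mode_scale_relation(self, rng):
        c = rng.normal(size=(3, 30, 3))
        _, m_mean = rms_repeat(c, mode="mean")
        _, m_pair = rms_repeat(c, mode="pairwise")
        # identity: mean pairwise squared distance = 2R/(R-1) x squared
        # dispersion about the per-landmark mean (R = 3 here)
        per_mean, _ = rms_repeat(c, mode="mean")
        per_pair, _ = rms_repeat(c, mode="pairwise")
        np.testing.assert_allclose(per_pair, per_mean * np.sqrt(2 * 3 / 2), rtol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        c = rng.normal(size=(3, 15, 3)) * 10
        ang = 0.8
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = c @ R.T + np.array([5, 6, 7])
        _, m1 = rms_repeat(c)
        _, m2 = rms_repeat(moved)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_single_round_rejected(self, rng):
        with pytest.raises(ValueError):
            rms_repeat(rng.normal(size=(1, 5, 3)))


class TestRmsBetween:
    def test_identical_observers_zero(self, rng):
        a = rng.normal(size=(12, 3))
        per, summary = rms_between([a, a.copy(), a.copy()])
        assert summary["Mean"].iloc[0] == 0.0

    def test_uniform_offset(self, rng):
        a = rng.normal(size=(8, 3))
        per, summary = rms_between([a, a + [1.0, 0, 0]])
        assert summary["Mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert summary["Std"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_observer_skill_ordering_recovered(self):
        # observers with noise 0.3/0.6/0.9 mm: intra-observer RMS ordering
        # O1 < O2 < O3 recovered in >= 95% of replicates
        rng = np.random.default_rng(11)
        sigmas = [0.3, 0.6, 0.9]
        K, R = 20, 3
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            truth = rng.normal(size=(K, 3)) * 40
            intra = []
            for s in sigmas:
                rounds = truth + rng.normal(scale=s, size=(R, K, 3))
                intra.append(rms_repeat(rounds)[1])
            wins += intra[0] < intra[1] < intra[2]
        assert wins / n_rep >= 0.95


class TestIcc:
    def test_identical_raters_perfect(self, rng):
        col = rng.normal(size=(8, 1)) * 5
        y = col.repeat(3, axis=1)
        assert icc(y, "two_way_consistency").icc == pytest.approx(1.0)
        assert icc(y, "two_way_agreement").icc == pytest.approx(1.0)

    def test_rater_bias_separates_models(self, rng):
        subj = rng.normal(scale=10, size=(20, 1))
        bias = np.array([[0.0, 3.0, -3.0]])
        y = subj + bias + rng.normal(scale=1e-4, size=(20, 3))
        c = icc(y, "two_way_consistency")
        a = icc(y, "two_way_agreement")
        assert c.icc > 0.999
        assert a.icc < 0.95
        assert a.icc <= c.icc

    def test_agreement_never_exceeds_consistency_with_bias(self, rng):
        for _ in range(20):
            y = (rng.normal(scale=5, size=(10, 1))
                 + rng.normal(scale=2, size=(1, 4))
                 + rng.normal(scale=1, size=(10, 4)))
            assert icc(y, "two_way_agreement").icc <= icc(y, "two_way_consistency").icc + 1e-12

    def test_matches_independent_mean_squares_oracle(self, rng):
        y = rng.normal(size=(6, 3)) * 4 + rng.normal(size=(6, 1)) * 7
        n, k = y.shape
        # brute-force two-way ANOVA mean squares
        g = y.mean()
        msr = k * sum((y[i].mean() - g) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((y[:, j].mean() - g) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (y[i, j] - y[i].mean() - y[:, j].mean() + g) ** 2
            for i in range(n) for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expect_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        expect_c = (msr - mse) / (msr + (k - 1) * mse)
        assert icc(y, "two_way_agreement").icc == pytest.approx(expect_a, abs=1e-12)
        assert icc(y, "two_way_consistency").icc == pytest.approx(expect_c, abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(9, 3)) + rng.normal(size=(9, 1)) * 3
        df = pd.DataFrame({
            "s": np.repeat(np.arange(9), 3),
            "r": np.tile(np.arange(3), 9),
            "y": y.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        # single-measure rows: absolute agreement then consistency
        ref_a = ref.iloc[1]  # ICC(A,1)
        ref_c = ref.iloc[2]  # ICC(C,1)
        mine_a = icc(y, "two_way_agreement")
        mine_c = icc(y, "two_way_consistency")
        assert mine_a.icc == pytest.approx(ref_a["ICC"], abs=1e-9)
        assert mine_c.icc == pytest.approx(ref_c["ICC"], abs=1e-9)
        assert mine_a.ci_low == pytest.approx(ref_a["CI95"][0], abs=0.01)
        assert mine_a.ci_high == pytest.approx(ref_a["CI95"][1], abs=0.01)

    def test_zero_variance_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icc(np.full((5, 3), 2.0))

    def test_ci_brackets_estimate(self, rng):
        y = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        for model in ["two_way_agreement", "two_way_consistency"]:
            r = icc(y, model)
            assert r.ci_low <= r.icc <= r.ci_high


class TestBlandAltman:
    def test_equal_measurements(self, rng):
        a = rng.normal(size=20)
        bias, lo, hi = bland_altman(a, a.copy())
        assert bias == 0 and lo == 0 and hi == 0

    def test_constant_offset_bias(self, rng):
        a = rng.normal(size=30) * 10
        bias, lo, hi = bland_altman(a, a - 0.4)
        assert bias == pytest.approx(0.4, abs=1e-12)

    def test_limits_at_unit_sd(self):
        # constructed diffs with sd exactly 1
        diffs = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0]) * np.sqrt(5 / 6)
        a = np.arange(6, dtype=float)
        bias, lo, hi = bland_altman(a + diffs, a)
        assert hi - bias == pytest.approx(1.96, abs=1e-9)
        assert bias - lo == pytest.approx(1.96, abs=1e-9)

    def test_plot_written(self, tmp_path, rng):
        a = rng.normal(size=15)
        bland_altman(a, a + rng.normal(size=15), plot_path=tmp_path / "ba.png")
        assert (tmp_path / "ba.png").exists()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestAnovaCentroid:
    def test_two_by_two_closed_form(self):
        # balanced 2x2 with 2 reps per cell and known cell means
        rows = []
        cell_means = {("a", "x"): 10.0, ("a", "y"): 12.0,
                      ("b", "x"): 14.0, ("b", "y"): 16.0}
        eps = [0.5, -0.5]
        for (f1, f2), m in cell_means.items():
            for e in eps:
                rows.append({"skull": f1, "method": f2, "centroid_size": m + e})
        tab = anova_centroid(pd.DataFrame(rows), terms=("skull", "method"))
        # main effects: SS_skull = 8*(2)^2 = 32, SS_method = 8*(1)^2 = 8
        assert tab.loc["skull", "Sum Sq"] == pytest.approx(32.0, abs=1e-9)
        assert tab.loc["method", "Sum Sq"] == pytest.approx(8.0, abs=1e-9)
        assert tab.loc["Residuals", "Sum Sq"] == pytest.approx(8 * 0.25, abs=1e-9)

    def test_skull_only_signal(self, rng):
        rows = []
        for s in range(10):
            for o in range(3):
                for m in ["man", "auto"]:
                    rows.append({"skull": s, "observer": o, "method": m,
                                 "centroid_size": 100 + 5 * s + rng.normal(0, 0.1)})
        tab = anova_centroid(pd.DataFrame(rows),
                             terms=("skull", "observer", "method"))
        assert tab.loc["skull", "F value"] > 1000
        assert tab.loc["method", "Sum Sq"] < 0.5
        assert tab.loc["observer", "Sum Sq"] < 0.5

    def test_ss_partition_and_df(self, rng):
        rows = []
        for s in range(6):
            for o in range(3):
                for it in range(2):
                    rows.append({"skull": s, "observer": o, "iteration": it,
                                 "centroid_size": rng.normal(50, 3)})
        df = pd.DataFrame(rows)
        tab = anova_centroid(df, terms=("skull", "observer/iteration"))
        y = df["centroid_size"]
        total_ss = ((y - y.mean()) ** 2).sum()
        assert tab["Sum Sq"].sum() == pytest.approx(total_ss, rel=1e-9)
        assert tab["Df"].sum() == len(df) - 1

    def test_nested_term_expansion(self, rng):
        rows = []
        for o in range(3):
            for it in range(3):
                for _ in range(2):
                    rows.append({"observer": o, "iteration": it,
                                 "centroid_size": rng.normal()})
        tab = anova_centroid(pd.DataFrame(rows), terms=("observer/iteration",))
        assert "observer" in tab.index
        assert any(":" in str(i) for i in tab.index)

    def test_rank_deficient_rejected(self):
        df = pd.DataFrame({
            "skull": [0, 0, 1, 1], "copy": [0, 0, 1, 1],
            "centroid_size": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError):
            anova_centroid(df, terms=("skull", "copy"))


class TestVarianceDecomposition:
    def test_pure_skull_signal(self, rng):
        S, O = 8, 3
        skull_shapes = rng.normal(size=(S, 10, 3)) * 5
        shapes = np.repeat(skull_shapes, O, axis=0)
        factors = pd.DataFrame({
            "skull": np.repeat(np.arange(S), O),
            "observer": np.tile(np.arange(O), S),
        })
        out = shape_variance_decomposition(shapes, factors, ("skull", "observer"),
                                           n_permutations=49, seed=0)
        assert out[out["term"] == "skull"]["R2"].iloc[0] > 0.999

    def test_injected_r2_recovered(self, rng):
        # construct data whose skull effect explains exactly 94% of SS
        S, m, p = 10, 6, 30
        E = np.repeat(rng.normal(size=(S, p)), m, axis=0)
        R = rng.normal(size=(S * m, p))
        # orthogonalize residuals against the skull space and the mean
        groups = np.repeat(np.arange(S), m)
        for s in range(S):
            R[groups == s] -= R[groups == s].mean(0)
        E -= E.mean(0)
        E *= np.sqrt(0.94) / np.linalg.norm(E)
        R *= np.sqrt(0.06) / np.linalg.norm(R)
        Y = E + R
        factors = pd.DataFrame({"skull": groups})
        out = shape_variance_decomposition(Y, factors, ("skull",),
                                           n_permutations=49, seed=1)
        r2 = out[out["term"] == "skull"]["R2"].iloc[0]
        assert r2 == pytest.approx(0.94, abs=0.03)

    def test_null_factor_pvalues_uniform(self):
        # independent null datasets: permutation p-values roughly uniform
        factors = pd.DataFrame({"grp": np.repeat([0, 1, 2], 10)})
        pvals = []
        for seed in range(25):
            Y = np.random.default_rng(1000 + seed).normal(size=(30, 12))
            out = shape_variance_decomposition(Y, factors, ("grp",),
                                               n_permutations=99, seed=seed)
            pvals.append(out["p_perm"].iloc[0])
        assert 0.3 < np.mean(pvals) < 0.7
        assert (np.array(pvals) < 0.05).mean() <= 0.2

    def test_r2_sums_to_one(self, rng):
        Y = rng.normal(size=(24, 9))
        factors = pd.DataFrame({
            "a": np.repeat([0, 1, 2], 8), "b": np.tile([0, 1], 12),
        })
        out = shape_variance_decomposition(Y, factors, ("a", "b"),
                                           n_permutations=19, seed=2)
        assert out["R2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_level_factor_rejected(self, rng):
        Y = rng.normal(size=(6, 9))
        factors = pd.DataFrame({"a": np.zeros(6, int)})
        with pytest.raises(ValueError):
            shape_variance_decomposition(Y, factors, ("a",))


class TestResidualizeAndPca:
    def test_uncorrelated_covariate_keeps_shapes(self, rng):
        Y = rng.normal(size=(40, 12))
        cov = pd.DataFrame({"age": rng.normal(size=40)})
        out = residualize_covariates(Y, cov)
        # noise fit removes only ~1/n of the variance
        assert np.corrcoef(Y.ravel(), out.ravel())[0, 1] > 0.9

    def test_linear_effect_removed(self, rng):
        n, p = 50, 20
        beta = rng.normal(size=p)
        age = rng.normal(size=n)
        Y = np.outer(age, beta) * 3 + rng.normal(scale=0.3, size=(n, p))
        out = residualize_covariates(Y, pd.DataFrame({"age": age}))
        # variance along the beta direction collapses
        proj_before = Y @ beta / np.linalg.norm(beta)
        proj_after = out @ beta / np.linalg.norm(beta)
        assert proj_after.var() < 0.05 * proj_before.var()
        # refit slope is ~0
        slope = np.polyfit(age, proj_after, 1)[0]
        assert abs(slope) < 0.1 * abs(np.polyfit(age, proj_before, 1)[0])

    def test_constant_covariate_dropped(self, rng):
        Y = rng.normal(size=(10, 6))
        out = residualize_covariates(Y, pd.DataFrame({"c": np.ones(10)}))
        np.testing.assert_allclose(out, Y)

    def test_pca_two_shapes_one_mode(self, rng):
        Y = rng.normal(size=(2, 15))
        vals, vecs, scores = shape_pca(Y)
        assert (vals[1:] < 1e-20).all()

    def test_pca_single_mode_dominates(self, rng):
        direction = rng.normal(size=30)
        Y = np.outer(rng.normal(size=25), direction) + rng.normal(scale=0.01,
                                                                  size=(25, 30))
        vals, _, _ = shape_pca(Y)
        assert vals[0] / vals.sum() > 0.95

    def test_pca_full_reconstruction(self, rng):
        Y = rng.normal(size=(8, 12))
        vals, vecs, scores = shape_pca(Y)
        recon = Y.mean(0) + scores @ vecs
        np.testing.assert_allclose(recon, Y, atol=1e-9)

    def test_eigenvalues_non_increasing(self, rng):
        vals, _, _ = shape_pca(rng.normal(size=(20, 40)))
        assert (np.diff(vals) <= 1e-12).all()
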