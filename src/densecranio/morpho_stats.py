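"""Reliability and accuracy statistics for landmark configurations.

Covers the validation battery of a landmarking study: RMS repeatability
within and between observers, intraclass correlation of centroid sizes with
F-based confidence intervals, Bland-Altman agreement, fixed-effects ANOVA on
centroid size, Procrustes variance decomposition over study factors with
permutation tests, PLSR covariate removal, and shape PCA.

Conventions: a "configuration" is a (K, 3) array of named landmarks in mm; a
repeated study is indexed (skull, observer, round, K, 3).  RMS dispersion is
measured about the per-landmark mean over repeats (comparable between the
manual and automated cases); the mean-pairwise alternative is available via
``mode="pairwise"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .template_builder import centroid_size, gpa  # noqa: F401  (re-exported)

log = logging.getLogger(__name__)

__all__ = [
    "centroid_size",
    "rms_repeat",
    "rms_between",
    "IccResult",
    "icc",
    "bland_altman",
    "anova_centroid",
    "shape_variance_decomposition",
    "residualize_covariates",
    "shape_pca",
]


# ---------------------------------------------------------------------------
# RMS repeatability
# ---------------------------------------------------------------------------


def rms_repeat(
    configs: np.ndarray, mode: str = "mean"
) -> tuple[np.ndarray, float]:
    """Repeatability of R repeated (K,3) configurations.

    ``mode="mean"``: per landmark, RMS distance of the R placements to their
    mean (dispersion about the centroid of repeats).  ``mode="pairwise"``:
    RMS over all pairwise distances, a sqrt(2R/(R-1))-scale alternative.
    Returns (per-landmark RMS (K,), mean over landmarks).
    """
    configs = np.asarray(configs, float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("need R >= 2 configurations of shape (K, 3)")
    if mode == "mean":
        center = configs.mean(axis=0)
        sq = ((configs - center) ** 2).sum(axis=2)  # (R, K)
        per_landmark = np.sqrt(sq.mean(axis=0))
    elif mode == "pairwise":
        pairs = list(combinations(range(configs.shape[0]), 2))
        sq = np.stack(
            [((configs[i] - configs[j]) ** 2).sum(axis=1) for i, j in pairs]
        )
        per_landmark = np.sqrt(sq.mean(axis=0))
    else:
        raise ValueError("mode must be 'mean' or 'pairwise'")
    return per_landmark, float(per_landmark.mean())


def rms_between(
    observer_means: Sequence[np.ndarray], names: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-observer RMS between per-observer mean configurations.

    Per landmark: RMS of pairwise inter-observer distances.  Returns
    ``(per_landmark, summary)`` where summary holds Mean/Std/Min/Max over
    landmarks, the usual reliability-table shape.
    """
    arrs = [np.asarray(a, float) for a in observer_means]
    K = arrs[0].shape[0]
    if any(a.shape != (K, 3) for a in arrs):
        raise ValueError("observer configurations must share K")
    if len(arrs) < 2:
        raise ValueError("need at least 2 observers")
    pairs = list(combinations(range(len(arrs)), 2))
    sq = np.stack([((arrs[i] - arrs[j]) ** 2).sum(axis=1) for i, j in pairs])
    per_landmark = np.sqrt(sq.mean(axis=0))
    names = list(names) if names is not None else [f"lm{k}" for k in range(K)]
    per = pd.DataFrame({"landmark": names, "rms_mm": per_landmark})
    summary = pd.DataFrame(
        [{
            "Mean": per_landmark.mean(), "Std": per_landmark.std(ddof=1),
            "Min": per_landmark.min(), "Max": per_landmark.max(),
        }]
    )
    return per, summary


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str  # two_way_agreement | two_way_consistency
    unit: str = "single"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("CI must bracket the ICC estimate")


def _two_way_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    n, k = y.shape
    g = y.mean()
    msr = k * ((y.mean(1) - g) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(0) - g) ** 2).sum() / (k - 1)
    sse = ((y - g) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(ratings: np.ndarray, model: str = "two_way_agreement",
        alpha: float = 0.05) -> IccResult:
    """Single-measure two-way ICC from a complete subject x rater matrix.

    ``two_way_consistency`` (ICC(3,1)) ignores rater bias;
    ``two_way_agreement`` (ICC(2,1)) penalizes it.  95% CIs use the standard
    F-based bounds (Satterthwaite approximation for agreement).
    """
    y = np.asarray(ratings, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("ratings must be (subjects >= 2) x (raters >= 2)")
    if not np.isfinite(y).all():
        raise ValueError("ratings must be complete (no missing cells)")
    n, k = y.shape
    msr, msc, mse = _two_way_mean_squares(y)
    if msr < 1e-30 and mse < 1e-30:
        raise ZeroDivisionError("zero variance everywhere; ICC undefined")
    if model == "two_way_consistency":
        val = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif model == "two_way_agreement":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        a = k * val / (n * (1 - val)) if val < 1 else np.inf
        b = 1 + k * val * (n - 1) / (n * (1 - val)) if val < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
        else:
            v = (n - 1) * (k - 1)
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        raise ValueError("model must be two_way_agreement or two_way_consistency")
    lo, hi = min(lo, val), max(hi, val)
    return IccResult(float(val), float(lo), float(hi), model)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def bland_altman(
    a: np.ndarray, b: np.ndarray, plot_path=None
) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement between paired measurements.

    bias = mean(a - b); limits = bias +/- 1.96 * sd(a - b).  Writes the
    difference-vs-mean plot when ``plot_path`` is given.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) != len(b):
        raise ValueError("paired measurements must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter((a + b) / 2, diff, s=14)
        for yv, style in [(bias, "-"), (lo, "--"), (hi, "--")]:
            ax.axhline(yv, color="k", linestyle=style, linewidth=0.8)
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=110)
        plt.close(fig)
    return bias, lo, hi


# ---------------------------------------------------------------------------
# ANOVA on centroid size
# ---------------------------------------------------------------------------


def _expand_terms(terms: Sequence[str]) -> list[str]:
    """Expand nesting 'a/b' into 'a' + 'a:b' and wrap factors in C()."""
    out: list[str] = []
    for t in terms:
        if "/" in t:
            a, b = (s.strip() for s in t.split("/", 1))
            for piece in (f"C({a})", f"C({a}):C({b})"):
                if piece not in out:
                    out.append(piece)
        elif ":" in t:
            out.append(":".join(f"C({s.strip()})" for s in t.split(":")))
        else:
            out.append(f"C({t.strip()})")
    return out


def anova_centroid(
    table: pd.DataFrame,
    response: str = "centroid_size",
    terms: Sequence[str] = ("skull", "observer", "method"),
) -> pd.DataFrame:
    """Sequential (type-I) fixed-effects ANOVA on centroid sizes.

    ``terms`` may contain plain factors, interactions ``"a:b"`` and nesting
    ``"a/b"`` (expands to a + a:b).  Returns a table with columns Df, Sum Sq,
    Mean Sq, F value, Pr(>F) plus a Residuals row, ordered as given.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    expanded = _expand_terms(terms)
    formula = f"{response} ~ " + " + ".join(expanded)
    fit = smf.ols(formula, data=table).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms among {expanded}")
    aov = sm.stats.anova_lm(fit, typ=1)
    out = aov.rename(
        columns={"df": "Df", "sum_sq": "Sum Sq", "mean_sq": "Mean Sq",
                 "F": "F value", "PR(>F)": "Pr(>F)"}
    )
    out.index = [i.replace("C(", "").replace(")", "") for i in out.index]
    out.index = [i if i != "Residual" else "Residuals" for i in out.index]
    return out


# ---------------------------------------------------------------------------
# Procrustes variance decomposition (MANOVA-style R^2)
# ---------------------------------------------------------------------------


def _design_columns(table: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    combo = table[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "|" + table[p].astype(str)
    dummies = pd.get_dummies(combo, drop_first=False).to_numpy(float)
    return dummies


def shape_variance_decomposition(
    aligned: np.ndarray,
    factors: pd.DataFrame,
    terms: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential decomposition of total Procrustes sum of squares.

    ``aligned`` is (n, Q, 3) or (n, p) GPA-aligned coordinates; each term's
    R^2 is its sequential increment in explained SS over the total centered
    SS.  Permutation p-values shuffle the residuals of the reduced model
    (seeded, ``n_permutations`` rounds).
    """
    Y = np.asarray(aligned, float)
    Y = Y.reshape(len(Y), -1)
    n = len(Y)
    if len(factors) != n:
        raise ValueError("factor table must align with shapes")
    for t in terms:
        for col in t.replace(":", "/").split("/"):
            if factors[col].nunique() < 2:
                raise ValueError(f"factor {col!r} has a single level")
    expanded: list[str] = []
    for t in terms:
        if "/" in t:
            a, b = t.split("/", 1)
            expanded += [a, f"{a}:{b}"]
        else:
            expanded.append(t)
    Yc = Y - Y.mean(0)
    ss_total = float((Yc**2).sum())
    rng = np.random.default_rng(seed)

    # hat matrices of nested models: intercept-only up to the full model
    hats = [np.full((n, n), 1.0 / n)]
    X = np.ones((n, 1))
    for t in expanded:
        X = np.hstack([X, _design_columns(factors, t)])
        # pseudo-inverse projection tolerates the over-complete dummy coding
        hats.append(X @ np.linalg.pinv(X))

    rows = []
    for k, t in enumerate(expanded):
        H_red, H_full = hats[k], hats[k + 1]
        M = H_full - H_red
        ss_obs = float(((M @ Y) ** 2).sum())
        resid = Y - H_red @ Y
        fitted = H_red @ Y
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ss_p = float(((M @ (fitted + resid[perm])) ** 2).sum())
            if ss_p >= ss_obs - 1e-12:
                count += 1
        rows.append(
            {"term": t, "SS": ss_obs, "R2": ss_obs / ss_total,
             "p_perm": (count + 1) / (n_permutations + 1)}
        )
    ss_resid = float(((Y - hats[-1] @ Y) ** 2).sum())
    rows.append({"term": "Residuals", "SS": ss_resid, "R2": ss_resid / ss_total,
                 "p_perm": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PLSR covariate removal and PCA
# ---------------------------------------------------------------------------


def residualize_covariates(
    shapes: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """Remove covariate effects from flattened shapes via PLSR.

    One PLS component per covariate; returns the residual shapes with the
    mean shape added back.  Constant covariates are dropped with a warning.
    """
    from sklearn.cross_decomposition import PLSRegression

    Y = np.asarray(shapes, float)
    Y = Y.reshape(len(Y), -1)
    X = covariates.copy()
    for col in list(X.columns):
        if X[col].nunique() < 2:
            log.warning("dropping constant covariate %r", col)
            X = X.drop(columns=[col])
    if X.shape[1] == 0:
        return Y.copy()
    Xv = X.to_numpy(float)
    if not np.isfinite(Xv).all():
        raise ValueError("covariates must be complete and numeric")
    n_comp = min(Xv.shape[1], len(Y) - 1, Y.shape[1])
    pls = PLSRegression(n_components=n_comp, scale=True)
    pls.fit(Xv, Y)
    predicted = pls.predict(Xv)
    return Y - predicted + Y.mean(0)


def shape_pca(shapes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of aligned flattened coordinates.

    Returns (eigenvalues non-increasing, eigenvectors as rows, scores);
    ``mean + scores @ eigenvectors`` reconstructs the input exactly when all
    components are kept.
    """
    Y = np.asarray(shapes, float)
    Y = Y.reshape(len(Y), -1)
    if len(Y) < 2:
        raise ValueError("need at least 2 shapes")
    mu = Y.mean(0)
    U, s, Vt = np.linalg.svd(Y - mu, full_matrices=False)
    eigvals = s**2 / (len(Y) - 1)
    scores = U * s
    return eigvals, Vt, scores
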