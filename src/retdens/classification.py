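"""Logistic classification on tangent-PCA scores with leave-one-out CV.

The density-based feature pipeline for one binary comparison: per LOOCV
fold, recompute the Karcher mean and tangent PCA on the n-1 training
subjects (no leakage of the held-out subject into feature construction),
fit a logistic model on the training scores, and score the held-out subject
via projection.  The n cross-validated probabilities are summarised by the
Mann-Whitney AUC with a Wald confidence interval from DeLong's variance
estimator (at a Bonferroni-corrected level), sensitivity/specificity at a
probability threshold, and the Brier score.  A five-number-summary baseline
(mean, min, max, Q1, Q3 of the raw micrometre values) feeds the same LOOCV
logistic path for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .sphere_geometry import (
    DensityFunction,
    SRTFunction,
    _karcher_stack,
    _log_rows,
    srt,
    trapezoid_weights,
)
from .tangent_pca import fit_tangent_pca

__all__ = [
    "LogisticModel",
    "ClassifierConfig",
    "ClassificationReport",
    "fit_logistic",
    "predict_prob",
    "auc_mann_whitney",
    "delong_auc_ci",
    "bonferroni_level",
    "brier",
    "sens_spec",
    "summary_feature_baseline",
    "loocv_evaluate",
]


@dataclass
class LogisticModel:
    """Coefficients beta = (intercept, slopes...) of a logistic model."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("logistic coefficients must be finite")


@dataclass
class ClassifierConfig:
    """Knobs of the LOOCV evaluation; defaults mirror the study settings."""

    variance_threshold: float = 0.9999
    ci_overall_alpha: float = 0.05
    ci_comparisons: int = 3
    threshold: float | str = 0.5  # or "youden"
    pca_scope: str = "per_fold"   # or "global"
    center_tangent: bool = True
    ridge: float = 1e-6
    karcher_tol: float = 1e-6
    karcher_step: float = 0.5
    karcher_max_iter: int = 100


@dataclass
class ClassificationReport:
    p_hat: np.ndarray
    y: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    ci_level: float
    sensitivity: float
    specificity: float
    brier: float
    threshold: float
    n_per_group: dict[int, int]
    feature_set: str


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LogisticModel:
    """Maximum-likelihood logistic fit with a small ridge on the slopes.

    The ridge (1e-6 by default, intercept unpenalised) guards against
    quasi-separation in small LOOCV folds while leaving well-conditioned
    fits essentially unchanged.  Deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_logistic requires exactly two classes in y")
    y01 = (y == classes.max()).astype(int)
    if X.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if X.shape[1] == 0:
        p = float(np.clip(y01.mean(), 1e-12, 1 - 1e-12))
        return LogisticModel(beta=np.array([np.log(p / (1 - p))]))
    clf = LogisticRegression(C=0.5 / ridge, solver="lbfgs", tol=1e-10, max_iter=5000)
    with warnings.catch_warnings():
        # quasi-separated folds plateau near the ridge-bounded optimum;
        # the probabilities are already stable there
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y01)
    return LogisticModel(beta=np.concatenate([clf.intercept_, clf.coef_.ravel()]))


def predict_prob(model: LogisticModel, x: np.ndarray) -> np.ndarray:
    """p = 1 / (1 + exp(-x' beta)) with an implicit leading intercept."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.beta.size - 1:
        raise ValueError("feature dimension does not match the model")
    eta = model.beta[0] + x @ model.beta[1:]
    return 1.0 / (1.0 + np.exp(-eta))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[y == 1][:, None]
    neg = scores[y == 0][None, :]
    psi = (pos > neg).astype(float) + 0.5 * (pos == neg)
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)  # V10 (per positive), V01 (per negative)


def auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes, coded 0/1")
    v10, _ = _placements(scores, y)
    return float(v10.mean())


def delong_auc_ci(
    p_hat: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """AUC with a Wald CI from DeLong's structural-components variance.

    The variance is S10/n1 + S01/n0 with S10, S01 the sample variances of
    the per-positive and per-negative placement values.  Degenerate inputs
    (all scores tied, or a class of size 1) give zero variance and a point
    CI rather than an error.  The CI is clipped to [0, 1].
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    v10, v01 = _placements(p_hat, y)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    se = float(np.sqrt(s10 / v10.size + s01 / v01.size))
    z = float(norm.ppf(0.5 + level / 2.0))
    return auc, float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def bonferroni_level(overall_alpha: float, k: int) -> float:
    """Per-comparison confidence level 1 - alpha/k for k comparisons."""
    if not 0.0 < overall_alpha < 1.0:
        raise ValueError("overall_alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - overall_alpha / k


def brier(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between probabilities and 0/1 outcomes."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if p_hat.size == 0 or p_hat.shape != y.shape:
        raise ValueError("p_hat and y must be non-empty and of equal length")
    return float(np.mean((p_hat - y) ** 2))


def sens_spec(
    p_hat: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """(sensitivity, specificity) with p >= threshold predicted positive."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    pred = p_hat >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def _youden_threshold(p_hat: np.ndarray, y: np.ndarray) -> float:
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(p_hat):
        se, sp = sens_spec(p_hat, y, t)
        if se + sp - 1.0 > best_j + 1e-12:
            best_j, best_t = se + sp - 1.0, float(t)
    return best_t


def summary_feature_baseline(samples: Sequence[Any]) -> np.ndarray:
    """Five-number summary (mean, min, max, Q1, Q3) of each raw um sample.

    Quartiles use linear interpolation.  Unlike the density features, these
    are not invariant to affine rescaling of the thickness values.
    """
    rows = []
    for i, s in enumerate(samples):
        v = np.asarray(s.values if hasattr(s, "values") else s, dtype=float).ravel()
        if v.size == 0:
            name = getattr(s, "subject_id", "") or f"index {i}"
            raise ValueError(f"empty pixel sample for subject {name}")
        q1, q3 = np.percentile(v, [25.0, 75.0])
        rows.append([v.mean(), v.min(), v.max(), q1, q3])
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _fold_probability(
    H: np.ndarray,
    grid: np.ndarray,
    wq: np.ndarray,
    y: np.ndarray,
    i: int,
    mu: np.ndarray,
    cfg: ClassifierConfig,
) -> float:
    """Cross-validated probability for held-out subject i.

    ``mu`` is the Karcher mean of the training rows (H without row i); the
    tangent PCA and logistic model are fitted on training subjects only and
    the held-out SRT enters solely through projection.
    """
    n = H.shape[0]
    train = np.arange(n) != i
    ytr = y[train]
    if len(np.unique(ytr)) < 2:
        raise ValueError(f"fold {i}: training labels contain a single class")
    sqw = np.sqrt(wq)
    Vtr = _log_rows(mu, H[train], wq) * sqw
    pca = fit_tangent_pca(Vtr, cfg.variance_threshold, center=cfg.center_tangent)
    x_test = (_log_rows(mu, H[i : i + 1], wq) * sqw - pca.row_mean) @ pca.directions.T
    lm = fit_logistic(pca.scores, ytr, ridge=cfg.ridge)
    return float(predict_prob(lm, x_test)[0])


def _assemble_report(
    p_hat: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, feature_set: str
) -> ClassificationReport:
    level = bonferroni_level(cfg.ci_overall_alpha, cfg.ci_comparisons)
    auc, lo, hi = delong_auc_ci(p_hat, y, level)
    thr = _youden_threshold(p_hat, y) if cfg.threshold == "youden" else float(cfg.threshold)
    se, sp = sens_spec(p_hat, y, thr)
    return ClassificationReport(
        p_hat=p_hat,
        y=y,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        ci_level=level,
        sensitivity=se,
        specificity=sp,
        brier=brier(p_hat, y.astype(float)),
        threshold=thr,
        n_per_group={0: int(np.sum(y == 0)), 1: int(np.sum(y == 1))},
        feature_set=feature_set,
    )


def _loocv_features(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    n = X.shape[0]
    p = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {i}: training labels contain a single class")
        lm = fit_logistic(X[train], y[train], ridge=cfg.ridge)
        p[i] = float(predict_prob(lm, X[i : i + 1])[0])
    return p


def loocv_evaluate(
    densities: Sequence[DensityFunction] | None,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    *,
    features: np.ndarray | None = None,
    feature_set: str | None = None,
) -> ClassificationReport:
    """Leave-one-out evaluation of the density-based (or feature) classifier.

    Density path (default): per fold, the Karcher mean, tangent PCA (at the
    variance threshold) and logistic fit are recomputed from the n-1
    training subjects, and the held-out subject is scored by projection.
    With ``config.pca_scope == "global"`` the mean and PCA are fitted once
    on all subjects and only the logistic model is refitted per fold
    (faster, but the held-out subject leaks into feature construction).

    Feature path: pass ``features`` (n x p; e.g. the five-number summary)
    instead of densities to run the same per-fold logistic evaluation.
    """
    cfg = config or ClassifierConfig()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2 or set(np.unique(y)) - {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    if features is not None:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError("features and y lengths differ")
        p = _loocv_features(X, y, cfg)
        return _assemble_report(p, y, cfg, feature_set or "five-number-summary")
    if densities is None:
        raise ValueError("provide densities or features")
    if len(densities) != y.size:
        raise ValueError("densities and y lengths differ")
    hs = [srt(f) for f in densities]
    grid = hs[0].grid
    H = np.stack([h.values for h in hs])
    wq = trapezoid_weights(grid.size)
    n = H.shape[0]
    p = np.empty(n)
    if cfg.pca_scope == "per_fold":
        W = (np.ones((n, n)) - np.eye(n)) / (n - 1)
        mus, _, _, _ = _karcher_stack(
            H, W, wq, tol=cfg.karcher_tol, step=cfg.karcher_step, max_iter=cfg.karcher_max_iter
        )
        for i in range(n):
            p[i] = _fold_probability(H, grid, wq, y, i, mus[i], cfg)
    elif cfg.pca_scope == "global":
        W = np.full((1, n), 1.0 / n)
        mu, _, _, _ = _karcher_stack(
            H, W, wq, tol=cfg.karcher_tol, step=cfg.karcher_step, max_iter=cfg.karcher_max_iter
        )
        sqw = np.sqrt(wq)
        V = _log_rows(mu[0], H, wq) * sqw
        pca = fit_tangent_pca(V, cfg.variance_threshold, center=cfg.center_tangent)
        p = _loocv_features(pca.scores, y, cfg)
    else:
        raise ValueError(f"unknown pca_scope {cfg.pca_scope!r}")
    return _assemble_report(p, y, cfg, feature_set or "density-based")
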