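"""Regularized risk models: feature selection, scoring and stratification.

The prognostic model is an elastic-net-penalized regression on the radiomic
feature matrix: LASSO (mixing alpha = 1), ridge (alpha = 0) or elastic net
(0 < alpha < 1). The default selection outcome is the event indicator
(penalized logistic regression); a penalized Cox mode on the censored times
is available as a configuration switch. The continuous risk score of a
subject is the linear predictor of the fitted model on training-standardized
features; subjects are stratified into low/high risk by comparing scores
with a threshold derived from the *training* scores only (median by
default), and the two groups are compared with the survival machinery from
:mod:`mbrisk.survival_stats`.

The regularization path is tuned by cross-validated deviance over a
descending lambda grid (glmnet-style, data-derived by default); fold
assignment is seeded, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import KFold, StratifiedKFold

from .survival_stats import GroupComparison, compare_groups


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RiskModelConfig:
    """Penalty mixing, tuning grid and stratification rule."""

    alpha: float = 1.0                     # 1 = LASSO, 0 = ridge, else elastic net
    lambda_grid: tuple[float, ...] | None = None   # None: data-derived glmnet grid
    n_lambda: int = 15
    lambda_min_ratio: float = 0.01
    cv_folds: int = 5
    selection_outcome: str = "event_indicator_logistic"  # or "cox_partial_likelihood"
    threshold_rule: str = "train_median"   # or "train_quantile"
    threshold_quantile: float = 0.5
    seed: int = 0
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_grid is not None:
            grid = tuple(float(l) for l in self.lambda_grid)
            if not grid or any(l <= 0 for l in grid):
                raise ValueError("lambda grid must be non-empty and positive")
            if any(np.diff(grid) > 0):
                raise ValueError("lambda grid must be decreasing")
            self.lambda_grid = grid
        if self.selection_outcome not in ("event_indicator_logistic",
                                          "cox_partial_likelihood"):
            raise ValueError(f"unknown selection outcome {self.selection_outcome!r}")
        if self.threshold_rule not in ("train_median", "train_quantile"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Training-set per-column z-scoring; zero-variance columns recorded
    and dropped."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing[:5]} ...")
        arr = np.ascontiguousarray(X[self.feature_names].to_numpy(float))
        return (arr - self.means) / self.sds


def standardize_features(train_X: pd.DataFrame, test_X: pd.DataFrame | None = None
                         ) -> tuple[np.ndarray, np.ndarray | None, FeatureScaler]:
    """Z-score features using training statistics only."""
    if len(train_X) < 2:
        raise ValueError("need at least 2 training rows")
    # compute on a C-contiguous array: results must not depend on the
    # DataFrame's internal block layout
    arr = np.ascontiguousarray(train_X.to_numpy(float))
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    scaler = FeatureScaler(
        feature_names=list(train_X.columns[keep]),
        means=means[keep],
        sds=sds[keep],
        dropped=list(train_X.columns[~keep]),
    )
    return (scaler.transform(train_X),
            scaler.transform(test_X) if test_X is not None else None,
            scaler)


# ---------------------------------------------------------------------------
# penalized fit
# ---------------------------------------------------------------------------

@dataclass
class RiskModelFit:
    """A fitted, tuned risk model plus everything needed to score new data."""

    scaler: FeatureScaler
    coefficients: np.ndarray          # aligned with scaler.feature_names
    intercept: float
    alpha: float
    lam: float
    threshold: float
    cv_deviance: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> dict[str, float]:
        return {n: float(c)
                for n, c in zip(self.scaler.feature_names, self.coefficients)
                if c != 0.0}

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "lambda": self.lam,
            "threshold": self.threshold,
            "intercept": self.intercept,
            "selected_features": self.selected_features,
            "dropped_zero_variance": self.scaler.dropped,
        }


def _logistic_estimator(alpha: float, lam: float, n: int, max_iter: int,
                        seed: int = 0) -> LogisticRegression:
    C = 1.0 / (lam * n)
    if alpha <= 0.0:
        return LogisticRegression(C=C, l1_ratio=0.0, solver="lbfgs",
                                  max_iter=max_iter, tol=1e-7)
    if alpha >= 1.0:  # coordinate-descent-style CD solver: fast, deterministic
        return LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear",
                                  max_iter=max_iter, tol=1e-6,
                                  random_state=seed)
    return LogisticRegression(C=C, l1_ratio=float(alpha), solver="saga",
                              max_iter=max_iter, tol=1e-4, random_state=seed)


def _auto_lambda_grid(X: np.ndarray, y: np.ndarray, cfg: RiskModelConfig
                      ) -> np.ndarray:
    """glmnet-style grid: log-spaced down from the smallest lambda that
    zeroes every coefficient."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(cfg.alpha, 1e-2))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def fit_regularized(train_X: pd.DataFrame, train_outcomes: pd.DataFrame,
                    cfg: RiskModelConfig = RiskModelConfig()) -> RiskModelFit:
    """Tune lambda by cross-validated deviance and fit the final model.

    ``train_outcomes`` must carry ``event`` (and ``time_days`` for the Cox
    mode). The stratification threshold (median of the training risk scores
    by default) is computed here, from training data only.
    """
    if len(train_X) < cfg.cv_folds:
        raise ValueError("fewer training rows than CV folds")
    Xs, _, scaler = standardize_features(train_X)

    if cfg.selection_outcome == "event_indicator_logistic":
        y = train_outcomes["event"].to_numpy(int)
        if len(np.unique(y)) < 2:
            raise ValueError("event indicator is constant; cannot fit logistic model")
        coefs, intercept, lam, cv_dev = _fit_logistic_path(Xs, y, cfg)
    else:
        coefs, intercept, lam, cv_dev = _fit_cox_path(Xs, train_outcomes, cfg)

    fit = RiskModelFit(scaler=scaler, coefficients=coefs, intercept=intercept,
                       alpha=cfg.alpha, lam=lam, threshold=0.0,
                       cv_deviance=cv_dev)
    train_scores = score_subjects(fit, train_X)
    q = 0.5 if cfg.threshold_rule == "train_median" else cfg.threshold_quantile
    fit.threshold = float(np.quantile(train_scores, q))
    return fit


def _fit_logistic_path(Xs: np.ndarray, y: np.ndarray, cfg: RiskModelConfig):
    grid = (np.asarray(cfg.lambda_grid) if cfg.lambda_grid is not None
            else _auto_lambda_grid(Xs, y.astype(float), cfg))
    n = len(y)
    n_splits = min(cfg.cv_folds, int(np.bincount(y).min()))
    cv_dev: dict[float, float] = {lam: 0.0 for lam in map(float, grid)}
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
        # warm-start one estimator per fold along the descending lambda path
        for tr, te in skf.split(Xs, y):
            est = _logistic_estimator(cfg.alpha, float(grid[0]), len(tr),
                                      cfg.max_iter, cfg.seed)
            est.set_params(warm_start=True)
            for lam in grid:
                est.set_params(C=1.0 / (float(lam) * len(tr)))
                est.fit(Xs[tr], y[tr])
                p = est.predict_proba(Xs[te])[:, 1]
                cv_dev[float(lam)] += log_loss(y[te], p, labels=[0, 1]) * len(te) / n
        lam_best = min(cv_dev, key=cv_dev.get)
    else:  # too few of one class to cross-validate: take the sparsest lambda
        cv_dev = {}
        lam_best = float(grid[0])
    est = _logistic_estimator(cfg.alpha, lam_best, n, cfg.max_iter, cfg.seed)
    est.fit(Xs, y)
    return est.coef_.ravel().copy(), float(est.intercept_[0]), lam_best, cv_dev


def _fit_cox_path(Xs: np.ndarray, outcomes: pd.DataFrame, cfg: RiskModelConfig):
    """Penalized Cox selection via scikit-survival's elastic-net Coxnet."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(outcomes["event"].to_numpy(bool),
                         outcomes["time_days"].to_numpy(float))
    l1r = max(cfg.alpha, 0.01)  # Coxnet requires a strictly positive L1 share
    grid = (np.asarray(cfg.lambda_grid) if cfg.lambda_grid is not None else None)
    kw = {"l1_ratio": l1r, "fit_baseline_model": False}
    if grid is not None:
        kw["alphas"] = grid
    else:
        kw["n_alphas"] = cfg.n_lambda
        kw["alpha_min_ratio"] = cfg.lambda_min_ratio

    cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    base = CoxnetSurvivalAnalysis(**kw)
    base.fit(Xs, y)
    alphas = np.asarray(base.alphas_)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    from sksurv.metrics import concordance_index_censored

    ev = outcomes["event"].to_numpy(bool)
    tm = outcomes["time_days"].to_numpy(float)
    for tr, te in cv.split(Xs):
        if ev[tr].sum() == 0 or ev[te].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=l1r, alphas=alphas,
                                   fit_baseline_model=False)
        m.fit(Xs[tr], y[tr])
        for k, a in enumerate(alphas):
            try:
                pred = m.predict(Xs[te], alpha=float(a))
                c = concordance_index_censored(ev[te], tm[te], pred)[0]
                scores[k] += c
                counts[k] += 1
            except ValueError:
                pass
    mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    # break ties toward the denser (smaller-lambda) end of the path
    k_best = len(alphas) - 1 - int(np.argmax(mean_scores[::-1]))
    lam_best = float(alphas[k_best])
    coefs = base.coef_[:, k_best].copy()
    cv_dev = {float(a): float(-s) for a, s in zip(alphas, mean_scores)}
    return coefs, 0.0, lam_best, cv_dev


def score_subjects(fit: RiskModelFit, X: pd.DataFrame) -> np.ndarray:
    """Continuous risk score: linear predictor on standardized features
    (higher score = higher predicted risk)."""
    Xs = fit.scaler.transform(X)
    return Xs @ fit.coefficients + fit.intercept


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

@dataclass
class StratificationResult:
    """Risk groups and survival comparison for one experiment cell."""

    scores: np.ndarray
    groups: np.ndarray                 # "low" / "high"
    threshold: float
    valid: bool
    comparison: GroupComparison | None
    metadata: dict = field(default_factory=dict)


def stratify(scores_train: np.ndarray, scores_test: np.ndarray,
             records_test, cfg: RiskModelConfig = RiskModelConfig(),
             threshold: float | None = None,
             metadata: dict | None = None) -> StratificationResult:
    """Split test subjects at the training-score threshold and compare the
    two survival groups. When every test subject falls on one side the
    comparison is flagged invalid (no p-value is reported).
    """
    scores_train = np.asarray(scores_train, dtype=float)
    scores_test = np.asarray(scores_test, dtype=float)
    if scores_train.size == 0 or scores_test.size == 0:
        raise ValueError("train and test scores must be nonempty")
    if threshold is None:
        q = 0.5 if cfg.threshold_rule == "train_median" else cfg.threshold_quantile
        threshold = float(np.quantile(scores_train, q))
    groups = np.where(scores_test > threshold, "high", "low")

    valid = len(np.unique(groups)) == 2
    comparison = None
    if valid:
        comparison = compare_groups(records_test, groups, risk_scores=scores_test)
    return StratificationResult(scores=scores_test, groups=groups,
                                threshold=threshold, valid=valid,
                                comparison=comparison,
                                metadata=metadata or {})


# ---------------------------------------------------------------------------
# univariate ranking
# ---------------------------------------------------------------------------

def feature_importance(X: pd.DataFrame, outcomes: Sequence[int]
                       ) -> list[tuple[str, float]]:
    """One-way ANOVA F statistic of every feature between the event and
    no-event groups, ranked descending."""
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(X.to_numpy(float), y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-F)
    return [(X.columns[i], float(F[i])) for i in order]


__all__ = [
    "RiskModelConfig",
    "RiskModelFit",
    "FeatureScaler",
    "StratificationResult",
    "standardize_features",
    "fit_regularized",
    "score_subjects",
    "stratify",
    "feature_importance",
]
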