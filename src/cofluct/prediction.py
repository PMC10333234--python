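"""Phenotype prediction from FC edge vectors under nested, grouped, confound-consistent CV.

The workhorse is kernel ridge regression with a Pearson kernel: the Gram
matrix holds the Pearson correlation between every pair of subjects' FC edge
vectors, and ridge regression is solved in its dual form,
(K + alpha I) c = y - mean(y). Hyperparameters are selected by an inner
5-fold CV nested inside the outer folds; with family structure, grouped
k-fold keeps families within one fold at both levels. Confounds (age, sex,
mean FD, ...) are removed from regression targets by an OLS model fitted on
the training partition only and applied to the test partition — never the
other way around. For classification (binary labels cannot be residualised)
the confounds are regressed from the features instead. Connectome-based
predictive modelling (CBPM) is provided as an independent robustness model:
edge-wise correlation screening at an uncorrected p threshold, summed
positive/negative networks, and a two-regressor linear model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import GroupKFold, KFold

logger = logging.getLogger(__name__)

#: l2-regularisation strengths searched by the inner CV for ridge models.
REGRESSION_ALPHA_GRID: tuple[float, ...] = (
    0, 0.00001, 0.0001, 0.001, 0.004, 0.007, 0.01, 0.04, 0.07, 0.1, 0.4, 0.7,
    1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 100,
    150, 200, 300, 500, 700, 1000, 10_000, 100_000, 1_000_000,
)

#: C grid for support-vector classifiers (kept for config completeness).
SVC_C_GRID: tuple[float, ...] = tuple(np.geomspace(0.01, 100, 50))

RIDGE_JITTER = 1e-10

ModelName = Literal["kernel_ridge", "cbpm", "ridge_classifier"]


# ---------------------------------------------------------------------------
# scoring (plain formula implementations)

def score(y: np.ndarray, y_hat: np.ndarray, metric: str) -> float:
    """Evaluate predictions: pearson_r, r2, mae, accuracy, or balanced_accuracy."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    n = len(y)
    if metric == "pearson_r":
        if np.std(y) == 0 or np.std(y_hat) == 0:
            raise ValueError("zero variance in y or y_hat")
        num = n * np.sum(y * y_hat) - np.sum(y) * np.sum(y_hat)
        den = (np.sqrt(n * np.sum(y ** 2) - np.sum(y) ** 2)
               * np.sqrt(n * np.sum(y_hat ** 2) - np.sum(y_hat) ** 2))
        return float(num / den)
    if metric == "r2":
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            raise ValueError("zero variance in y")
        return float(1.0 - np.sum((y - y_hat) ** 2) / sst)
    if metric == "mae":
        return float(np.mean(np.abs(y - y_hat)))
    if metric == "accuracy":
        return float(np.mean(y_hat == y))
    if metric == "balanced_accuracy":
        labels = np.unique(y)
        if len(labels) != 2:
            raise ValueError("balanced accuracy requires two classes in y")
        pos, neg = labels[1], labels[0]
        tp = np.sum((y == pos) & (y_hat == pos))
        fn = np.sum((y == pos) & (y_hat != pos))
        tn = np.sum((y == neg) & (y_hat == neg))
        fp = np.sum((y == neg) & (y_hat != neg))
        return float(0.5 * (tp / (tp + fn) + tn / (tn + fp)))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# confound removal

@dataclass
class ConfoundModel:
    """OLS coefficients of target-on-confounds, fitted on training subjects only."""

    coef: np.ndarray            # (n_confounds + 1,), intercept first
    kept_columns: list[int]

    def design(self, confounds: np.ndarray) -> np.ndarray:
        c = np.asarray(confounds, dtype=float)
        return np.column_stack([np.ones(len(c)), c[:, self.kept_columns]])

    def predict(self, confounds: np.ndarray) -> np.ndarray:
        return self.design(confounds) @ self.coef


def _fit_confound_model(train_targets: np.ndarray,
                        train_confounds: np.ndarray) -> ConfoundModel:
    c = np.asarray(train_confounds, dtype=float)
    # drop columns collinear with the intercept or earlier columns
    kept: list[int] = []
    base = np.ones((len(c), 1))
    for j in range(c.shape[1]):
        cand = np.column_stack([base, c[:, kept + [j]]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append(j)
        else:
            warnings.warn(f"dropping collinear confound column {j}",
                          RuntimeWarning, stacklevel=3)
    x = np.column_stack([np.ones(len(c)), c[:, kept]])
    coef, *_ = np.linalg.lstsq(x, np.asarray(train_targets, dtype=float),
                               rcond=None)
    return ConfoundModel(coef=coef, kept_columns=kept)


def residualize_targets(
    train_targets: np.ndarray, train_confounds: np.ndarray,
    test_targets: np.ndarray, test_confounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, ConfoundModel]:
    """CV-consistent confound removal: fit on train, residualise both partitions."""
    model = _fit_confound_model(train_targets, train_confounds)
    train_res = np.asarray(train_targets, float) - model.predict(train_confounds)
    test_res = np.asarray(test_targets, float) - model.predict(test_confounds)
    return train_res, test_res, model


def residualize_features(
    train_features: np.ndarray, train_confounds: np.ndarray,
    test_features: np.ndarray, test_confounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, ConfoundModel]:
    """Column-wise confound removal from features (classification recipe)."""
    model = _fit_confound_model(train_features, train_confounds)
    train_res = np.asarray(train_features, float) - model.predict(train_confounds)
    test_res = np.asarray(test_features, float) - model.predict(test_confounds)
    return train_res, test_res, model


# ---------------------------------------------------------------------------
# models

def pearson_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """K(i, j) = Pearson r between row i of ``a`` and row j of ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1] or a.shape[1] < 2:
        raise ValueError("need matching feature dimension with >= 2 edges")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((ac ** 2).sum(axis=1))
    bsd = np.sqrt((bc ** 2).sum(axis=1))
    if (asd == 0).any() or (bsd == 0).any():
        raise ValueError("constant feature row")
    return (ac @ bc.T) / np.outer(asd, bsd)


@dataclass
class KernelRidgeFit:
    dual_coef: np.ndarray
    intercept: float
    alpha: float

    def predict(self, k_test: np.ndarray) -> np.ndarray:
        return k_test @ self.dual_coef + self.intercept


def kernel_ridge(k_train: np.ndarray, y_train: np.ndarray,
                 alpha: float) -> KernelRidgeFit:
    """Dual ridge solve (K + alpha I) c = y - mean(y); alpha = 0 gets a tiny jitter."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    k = np.asarray(k_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    eff = alpha if alpha > 0 else RIDGE_JITTER
    if alpha == 0:
        logger.debug("alpha = 0: applying jitter %g", RIDGE_JITTER)
    mean = float(y.mean())
    a = k + eff * np.eye(len(k))
    try:
        c = np.linalg.solve(a, y - mean)
    except np.linalg.LinAlgError:
        c, *_ = np.linalg.lstsq(a, y - mean, rcond=None)
    return KernelRidgeFit(dual_coef=c, intercept=mean, alpha=alpha)


@dataclass
class RidgeClassifierFit:
    """Primal ridge on +/-1-coded labels; sign of the decision value predicts."""

    coef: np.ndarray
    intercept: float
    classes: np.ndarray
    alpha: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x) >= 0, self.classes[1], self.classes[0])


def ridge_classifier(x_train: np.ndarray, y_train: np.ndarray,
                     alpha: float) -> RidgeClassifierFit:
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ridge classifier requires exactly 2 classes")
    t = np.where(y == classes[1], 1.0, -1.0)
    eff = alpha if alpha > 0 else RIDGE_JITTER
    xm = x.mean(axis=0)
    tm = t.mean()
    xc = x - xm
    a = xc.T @ xc + eff * np.eye(x.shape[1])
    try:
        w = np.linalg.solve(a, xc.T @ (t - tm))
    except np.linalg.LinAlgError:
        w, *_ = np.linalg.lstsq(a, xc.T @ (t - tm), rcond=None)
    return RidgeClassifierFit(coef=w, intercept=float(tm - xm @ w),
                              classes=classes, alpha=alpha)


@dataclass
class CBPMFit:
    pos_edges: np.ndarray
    neg_edges: np.ndarray
    coef: np.ndarray            # intercept, pos-sum, neg-sum
    fallback: bool

    def _sums(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([
            np.ones(len(x)),
            x[:, self.pos_edges].sum(axis=1) if self.pos_edges.size else np.zeros(len(x)),
            x[:, self.neg_edges].sum(axis=1) if self.neg_edges.size else np.zeros(len(x)),
        ])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._sums(np.asarray(x, float)) @ self.coef


def cbpm_fit(train_features: np.ndarray, train_target: np.ndarray,
             p_threshold: float = 0.01) -> CBPMFit:
    """Connectome-based predictive modelling: screen, sum, regress.

    Edges correlating with the target on the training set at two-tailed
    p < ``p_threshold`` are split by correlation sign; per subject the edge
    values in each set are summed and a linear model of the target on the
    two sums is fitted. If no edge survives, an intercept-only model is used.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("CBPM needs at least 3 training subjects")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    xsd = np.sqrt((xc ** 2).sum(axis=0))
    ysd = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (xsd * ysd)
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    selected = p < p_threshold
    pos = np.flatnonzero(selected & (r > 0))
    neg = np.flatnonzero(selected & (r < 0))
    fallback = pos.size == 0 and neg.size == 0
    if fallback:
        warnings.warn("CBPM selected no edges; intercept-only fallback",
                      RuntimeWarning, stacklevel=2)
        return CBPMFit(pos_edges=pos, neg_edges=neg,
                       coef=np.array([y.mean(), 0.0, 0.0]), fallback=True)
    fit = CBPMFit(pos_edges=pos, neg_edges=neg, coef=np.zeros(3), fallback=False)
    design = fit._sums(x)
    # guard against a degenerate (all-zero) sum column
    keep = np.ptp(design, axis=0) > 0
    keep[0] = True
    coef = np.zeros(3)
    sol, *_ = np.linalg.lstsq(design[:, keep], y, rcond=None)
    coef[keep] = sol
    fit.coef = coef
    return fit


def cbpm(train_features: np.ndarray, train_target: np.ndarray,
         test_features: np.ndarray, p_threshold: float = 0.01) -> np.ndarray:
    """Fit CBPM on the training partition and predict the test partition."""
    return cbpm_fit(train_features, train_target, p_threshold).predict(test_features)


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class CVSpec:
    """Outer/inner CV layout. Grouped k-fold keeps families within one fold."""

    scheme: Literal["grouped_kfold", "repeated_kfold"] = "grouped_kfold"
    k_outer: int = 10
    n_repeats: int = 1
    k_inner: int = 5
    groups: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")
        if self.scheme == "grouped_kfold" and self.groups is None:
            raise ValueError("grouped_kfold requires groups")
        if self.scheme == "grouped_kfold" and self.n_repeats != 1:
            raise ValueError("grouped_kfold does not support repeats")

    def outer_splits(self, n: int):
        if self.scheme == "grouped_kfold":
            yield from GroupKFold(n_splits=self.k_outer).split(
                np.zeros(n), groups=np.asarray(self.groups))
        else:
            for rep in range(self.n_repeats):
                kf = KFold(n_splits=self.k_outer, shuffle=True,
                           random_state=self.seed + rep)
                yield from kf.split(np.zeros(n))

    def inner_splits(self, train_idx: np.ndarray):
        n = len(train_idx)
        if self.scheme == "grouped_kfold":
            g = np.asarray(self.groups)[train_idx]
            yield from GroupKFold(n_splits=self.k_inner).split(
                np.zeros(n), groups=g)
        else:
            kf = KFold(n_splits=self.k_inner, shuffle=True,
                       random_state=self.seed)
            yield from kf.split(np.zeros(n))


@dataclass
class FoldFit:
    """Everything fitted on one outer-training partition."""

    model_name: ModelName
    hyperparameter: float
    estimator: object
    confound_model: ConfoundModel | None
    feature_confound_model: ConfoundModel | None
    train_idx: np.ndarray
    features_train: np.ndarray

    def predict(self, features_test: np.ndarray,
                confounds_test: np.ndarray | None = None) -> np.ndarray:
        x_test = np.asarray(features_test, dtype=float)
        if self.feature_confound_model is not None:
            x_test = x_test - self.feature_confound_model.predict(confounds_test)
        if self.model_name == "kernel_ridge":
            k_test = pearson_kernel(x_test, self.features_train)
            return self.estimator.predict(k_test)
        return self.estimator.predict(x_test)


def _fit_estimator(model: ModelName, x_train: np.ndarray, y_train: np.ndarray,
                   param: float):
    if model == "kernel_ridge":
        return kernel_ridge(pearson_kernel(x_train, x_train), y_train, param)
    if model == "ridge_classifier":
        return ridge_classifier(x_train, y_train, param)
    if model == "cbpm":
        return cbpm_fit(x_train, y_train, p_threshold=param)
    raise ValueError(f"unknown model {model!r}")


def _predict_estimator(model: ModelName, est, x_train: np.ndarray,
                       x_test: np.ndarray) -> np.ndarray:
    if model == "kernel_ridge":
        return est.predict(pearson_kernel(x_test, x_train))
    return est.predict(x_test)


def fit_fold(
    features: np.ndarray,
    target: np.ndarray,
    confounds: np.ndarray | None,
    train_idx: np.ndarray,
    cv: CVSpec,
    model: ModelName,
    grid: Sequence[float],
    classification: bool,
) -> FoldFit:
    """Fit one outer fold: inner-CV hyperparameter selection + refit on the
    full outer-training partition. Only ``train_idx`` rows are ever touched,
    which is what makes the leakage audit possible.
    """
    features = np.asarray(features, dtype=float)
    target = np.asarray(target)
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    inner_metric = "accuracy" if classification else "pearson_r"

    if len(grid) > 1:
        per_split: list[np.ndarray] = []
        for tr, va in cv.inner_splits(train_idx):
            itr, iva = train_idx[tr], train_idx[va]
            x_tr, x_va = features[itr], features[iva]
            y_tr, y_va = target[itr], target[iva]
            if confounds is not None:
                if classification:
                    x_tr, x_va, _ = residualize_features(
                        x_tr, confounds[itr], x_va, confounds[iva])
                else:
                    y_tr, y_va, _ = residualize_targets(
                        y_tr, confounds[itr], y_va, confounds[iva])
            # the Gram matrices do not depend on the grid value: compute once
            if model == "kernel_ridge":
                k_tr = pearson_kernel(x_tr, x_tr)
                k_va = pearson_kernel(x_va, x_tr)
            col = np.full(len(grid), np.nan)
            for gi, param in enumerate(grid):
                if model == "kernel_ridge":
                    est = kernel_ridge(k_tr, y_tr, param)
                    y_hat = est.predict(k_va)
                else:
                    est = _fit_estimator(model, x_tr, y_tr, param)
                    y_hat = _predict_estimator(model, est, x_tr, x_va)
                try:
                    col[gi] = score(y_va, y_hat, inner_metric)
                except ValueError:
                    pass
            per_split.append(col)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_scores = np.nanmean(np.column_stack(per_split), axis=1)
        if np.all(np.isnan(mean_scores)):
            best = 0
        else:
            best = int(np.nanargmax(mean_scores))
    else:
        best = 0
    param = grid[best]

    x_tr = features[train_idx]
    y_tr = target[train_idx]
    conf_model = feat_conf_model = None
    if confounds is not None:
        if classification:
            feat_conf_model = _fit_confound_model(x_tr, confounds[train_idx])
            x_tr = x_tr - feat_conf_model.predict(confounds[train_idx])
        else:
            conf_model = _fit_confound_model(y_tr, confounds[train_idx])
            y_tr = y_tr - conf_model.predict(confounds[train_idx])
    est = _fit_estimator(model, x_tr, y_tr, param)
    return FoldFit(model_name=model, hyperparameter=param, estimator=est,
                   confound_model=conf_model,
                   feature_confound_model=feat_conf_model,
                   train_idx=np.asarray(train_idx), features_train=x_tr)


@dataclass
class PredictionResult:
    fold_scores: dict[str, list[float]]
    chosen_params: list[float]
    fold_fits: list[FoldFit] = field(default_factory=list)
    undefined_folds: list[int] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.fold_scores[metric]))

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m),
                "per_fold": [float(v) for v in vals]}
            for m, vals in self.fold_scores.items()
        } | {"chosen_params": [float(p) for p in self.chosen_params]}


def run_prediction_cv(
    features: np.ndarray,
    target: np.ndarray,
    confounds: np.ndarray | None,
    cv: CVSpec,
    model: ModelName = "kernel_ridge",
    grid: Sequence[float] | None = None,
    metrics: Sequence[str] = ("pearson_r",),
    keep_fits: bool = False,
) -> PredictionResult:
    """Nested cross-validated prediction of one target from FC edge features."""
    features = np.asarray(features, dtype=float)
    target = np.asarray(target)
    n = len(target)
    if features.shape[0] != n:
        raise ValueError("features and target must align on subjects")
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n:
            raise ValueError("confounds and target must align on subjects")
    classification = model == "ridge_classifier"
    if grid is None:
        grid = [0.01] if model == "cbpm" else list(REGRESSION_ALPHA_GRID)

    fold_scores: dict[str, list[float]] = {m: [] for m in metrics}
    chosen: list[float] = []
    fits: list[FoldFit] = []
    undefined: list[int] = []
    for fi, (train_idx, test_idx) in enumerate(cv.outer_splits(n)):
        if len(test_idx) < 2:
            raise ValueError(f"outer fold {fi} has fewer than 2 test subjects")
        fit = fit_fold(features, target, confounds, train_idx, cv, model,
                       grid, classification)
        conf_test = confounds[test_idx] if confounds is not None else None
        y_hat = fit.predict(features[test_idx], conf_test)
        y_test = target[test_idx]
        if fit.confound_model is not None:
            y_test = np.asarray(y_test, float) - fit.confound_model.predict(conf_test)
        for m in metrics:
            try:
                fold_scores[m].append(score(y_test, y_hat, m))
            except ValueError:
                logger.warning("fold %d: metric %s undefined", fi, m)
                fold_scores[m].append(float("nan"))
                if fi not in undefined:
                    undefined.append(fi)
        chosen.append(float(fit.hyperparameter))
        if keep_fits:
            fits.append(fit)
    return PredictionResult(fold_scores=fold_scores, chosen_params=chosen,
                            fold_fits=fits, undefined_folds=undefined)
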