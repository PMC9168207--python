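"""Feature ranking, classifiers, cross-validation and performance metrics.

Features are ranked by the absolute Welch (unequal-variance) two-sample t
statistic.  Nine classifiers are benchmarked under stratified 10-fold
cross-validation with fold-internal standardization (and, when a reducer
factory is supplied, fold-internal dimensionality reduction, so the test
folds never leak into fitting).  Confusion counts are pooled over folds;
the positive class is HTN, so sensitivity is the fraction of HTN images
found and specificity the fraction of normals cleared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

POSITIVE_LABEL = "htn"

CLASSIFIER_NAMES = (
    "DT",
    "DL",
    "DQ",
    "svmPoly_1",
    "svmPoly_2",
    "svmPoly_3",
    "svmRBF",
    "kNN",
    "probNN",
)


# -- probabilistic neural network -------------------------------------------


class ParzenWindowClassifier(ClassifierMixin, BaseEstimator):
    """Parzen-window Gaussian-kernel class-conditional density classifier.

    The classic probabilistic neural network: each training point contributes
    an isotropic Gaussian kernel of width ``sigma`` to its class density;
    prediction is the class with the largest prior-weighted density.
    """

    def __init__(self, sigma: float = 0.1):
        self.sigma = sigma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.classes_, counts = np.unique(y, return_counts=True)
        self.X_ = X
        self.y_ = y
        self.priors_ = counts / counts.sum()
        return self

    def _log_density(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.classes_.size))
        for j, cls in enumerate(self.classes_):
            Xc = self.X_[self.y_ == cls]
            d2 = ((X[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
            k = -d2 / (2.0 * self.sigma**2)
            # log-mean-exp for numerical stability
            m = k.max(axis=1)
            out[:, j] = m + np.log(np.exp(k - m[:, None]).mean(axis=1))
            out[:, j] += np.log(self.priors_[j])
        return out

    def predict(self, X):
        check_is_fitted(self, "X_")
        scores = self._log_density(X)
        return self.classes_[np.argmax(scores, axis=1)]


# -- classifier registry -----------------------------------------------------


def make_classifier(spec: str, seed: int = 0, **params) -> BaseEstimator:
    """Fresh classifier instance for a registry name."""
    if spec == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **params)
    if spec == "DL":
        return LinearDiscriminantAnalysis(**params)
    if spec == "DQ":
        return QuadraticDiscriminantAnalysis(**params)
    if spec in ("svmPoly_1", "svmPoly_2", "svmPoly_3"):
        degree = int(spec[-1])
        defaults = dict(kernel="poly", degree=degree, C=1.0, gamma="scale", coef0=1.0)
        defaults.update(params)
        return SVC(random_state=seed, **defaults)
    if spec == "svmRBF":
        defaults = dict(kernel="rbf", C=1.0, gamma="scale")
        defaults.update(params)
        return SVC(random_state=seed, **defaults)
    if spec == "kNN":
        defaults = dict(n_neighbors=5)
        defaults.update(params)
        return KNeighborsClassifier(**defaults)
    if spec == "probNN":
        defaults = dict(sigma=0.1)
        defaults.update(params)
        return ParzenWindowClassifier(**defaults)
    raise ValueError(f"unknown classifier spec {spec!r}; choose from {CLASSIFIER_NAMES}")


def train_predict(clf, Xtr, ytr, Xte, seed: int = 0, **params) -> np.ndarray:
    """Fit a classifier (spec name or estimator) and predict test labels.

    A singular covariance in the quadratic discriminant is ridge-repaired
    with a warning.
    """
    est = make_classifier(clf, seed=seed, **params) if isinstance(clf, str) else clone(clf)
    Xtr = np.asarray(Xtr, dtype=float)
    Xte = np.asarray(Xte, dtype=float)
    if isinstance(est, KNeighborsClassifier) and est.n_neighbors > Xtr.shape[0]:
        est.set_params(n_neighbors=Xtr.shape[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", np.linalg.LinAlgError)  # no-op, explicit
            est.fit(Xtr, ytr)
            return np.asarray(est.predict(Xte))
    except np.linalg.LinAlgError:
        if isinstance(est, QuadraticDiscriminantAnalysis):
            warnings.warn("singular covariance in DQ: refitting with ridge repair")
            est = QuadraticDiscriminantAnalysis(reg_param=1e-3)
            est.fit(Xtr, ytr)
            return np.asarray(est.predict(Xte))
        raise


# -- Welch t ranking ----------------------------------------------------------


@dataclass
class FeatureStats:
    """Per-feature two-class sample moments and the Welch t test."""

    index: int
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    p: float


@dataclass
class RankedFeatures:
    """Feature order sorted by descending |t| (ties by ascending index)."""

    order: np.ndarray
    stats: list[FeatureStats] = field(default_factory=list)


def welch_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Welch's t statistic (absolute value) and two-sided p-value.

    Degrees of freedom by Welch-Satterthwaite.  Requires n >= 2 per class and
    at least one nonzero standard deviation.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least two samples")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ValueError("degenerate variances: both classes constant")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = np.sqrt(v1 + v2)
    t = abs(m1 - m2) / se
    denom = 0.0
    if s1 > 0:
        denom += v1**2 / (n1 - 1)
    if s2 > 0:
        denom += v2**2 / (n2 - 1)
    df = (v1 + v2) ** 2 / denom
    p = float(2.0 * stats.t.sf(t, df)) if t > 0 else 1.0
    return float(t), min(p, 1.0)


def rank_features(X, y) -> RankedFeatures:
    """Rank columns of X by descending |Welch t| between the two classes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("rank_features requires exactly two classes")
    X1, X2 = X[y == classes[0]], X[y == classes[1]]
    n1, n2 = X1.shape[0], X2.shape[0]
    stats_list = []
    tvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        m1, s1 = X1[:, j].mean(), X1[:, j].std(ddof=1)
        m2, s2 = X2[:, j].mean(), X2[:, j].std(ddof=1)
        if s1 == 0 and s2 == 0:
            t, p = 0.0, 1.0  # identical across classes: ranked last
        else:
            t, p = welch_t(m1, s1, n1, m2, s2, n2)
        tvals[j] = t
        stats_list.append(FeatureStats(j, m1, s1, n1, m2, s2, n2, t, p))
    # stable sort on -|t| keeps ascending index order for ties
    order = np.argsort(-tvals, kind="stable")
    return RankedFeatures(order=order, stats=[stats_list[i] for i in order])


# -- metrics and cross-validation ---------------------------------------------


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int
) -> tuple[float, float, float, float]:
    """(accuracy, PPV, sensitivity, specificity) in percent.

    Undefined ratios (zero denominators) are returned as NaN with a warning.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero confusion counts")
    acc = 100.0 * (tp + tn) / total

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator")
            return float("nan")
        return 100.0 * num / den

    ppv = _ratio(tp, tp + fp, "PPV")
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    return acc, ppv, sens, spec


@dataclass
class CvReport:
    """Pooled cross-validation confusion counts and derived metrics (%)."""

    classifier: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    ppv: float
    sensitivity: float
    specificity: float
    n_features_used: int
    seed: int
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def cross_validate(
    X,
    y,
    clf: str | BaseEstimator = "DT",
    n_folds: int = 10,
    seed: int = 17,
    reducer=None,
    positive_label=POSITIVE_LABEL,
    clf_params: dict | None = None,
) -> CvReport:
    """Stratified k-fold CV with fold-internal standardization.

    ``reducer`` is an optional zero-argument factory returning a fresh
    supervised transformer (e.g. ``lambda: LSDA()``); it is fitted on each
    training fold only, so the evaluation is leakage-free.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("need at least one sample per fold")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if counts.min() < n_folds:
        raise ValueError("a fold would lose a class: too few samples per class")
    if positive_label not in classes:
        positive_label = classes[-1]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    fold_accs = []
    n_used = X.shape[1]
    for tr_idx, te_idx in skf.split(X, y):
        Xtr, Xte = X[tr_idx], X[te_idx]
        ytr, yte = y[tr_idx], y[te_idx]
        if reducer is not None:
            red = reducer()
            red.fit(Xtr, ytr)
            Xtr, Xte = red.transform(Xtr), red.transform(Xte)
            n_used = Xtr.shape[1]
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        pred = train_predict(clf, Xtr, ytr, Xte, seed=seed, **(clf_params or {}))
        pos_true = yte == positive_label
        pos_pred = pred == positive_label
        tp += int((pos_true & pos_pred).sum())
        fn += int((pos_true & ~pos_pred).sum())
        fp += int((~pos_true & pos_pred).sum())
        tn += int((~pos_true & ~pos_pred).sum())
        fold_accs.append(float((pred == yte).mean()))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc, ppv, sens, spec = metrics_from_confusion(tp, fp, tn, fn)
    return CvReport(
        classifier=clf if isinstance(clf, str) else type(clf).__name__,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=acc,
        ppv=ppv,
        sensitivity=sens,
        specificity=spec,
        n_features_used=n_used,
        seed=seed,
        fold_accuracies=fold_accs,
    )


def incremental_selection(
    X_ranked,
    y,
    clf: str | BaseEstimator = "DT",
    max_features: int = 10,
    n_folds: int = 10,
    seed: int = 17,
    **cv_kwargs,
) -> tuple[int, list[CvReport]]:
    """Accuracy-vs-k curve over the first k ranked features, k = 1..max.

    Returns the smallest k attaining the maximal accuracy and the full list
    of per-k reports.  Columns of ``X_ranked`` must already be in ranked
    order.
    """
    X_ranked = np.asarray(X_ranked, dtype=float)
    max_features = min(max_features, X_ranked.shape[1])
    reports = [
        cross_validate(
            X_ranked[:, :k], y, clf, n_folds=n_folds, seed=seed, **cv_kwargs
        )
        for k in range(1, max_features + 1)
    ]
    accs = np.array([r.accuracy for r in reports])
    best_k = int(np.argmax(accs)) + 1  # argmax returns the first (smallest) k
    return best_k, reports
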