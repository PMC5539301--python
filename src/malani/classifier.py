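"""The binary-classifier contract shared by all pipeline stages.

Every stage scores feature matrices by k-fold cross-validated accuracy of
a classifier built from a :class:`ClassifierSpec`.  The default is a
C-classification SVM with an RBF kernel, cost 1 and gamma equal to the
reciprocal of the feature count, with per-feature standardization fitted
on each training fold — the default behaviour of the reference SVM
implementation this configuration mirrors (an R ``e1071``-style
``svm(..., scale = TRUE)`` fit).  Random-forest and logistic-regression
families are available as drop-in alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import lightgbm as lgb
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

try:  # low-level libsvm entry points: identical fits, ~6x less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover - depends on sklearn internals
    _HAVE_LIBSVM = False

from .data import FoldPlan, MalaniError

__all__ = ["ClassifierSpec", "CVResult", "cv_accuracy", "build_estimator"]

Family = Literal["svm_rbf", "svm_linear", "random_forest", "logistic"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the per-stage classifier.

    Parameters
    ----------
    family : str
        One of ``svm_rbf`` (default), ``svm_linear``, ``random_forest``,
        ``logistic``.
    cost : float
        SVM regularisation parameter C (default 1).
    gamma : float or str
        RBF kernel width.  ``"reciprocal_of_feature_count"`` (default)
        uses 1/n_features; a positive float fixes it explicitly.
    scale : bool
        Standardize each feature to zero mean / unit variance using
        training-fold statistics (default True).  Tree ensembles are
        invariant to monotone per-feature rescaling, so the flag is a
        no-op for the random-forest family.
    metric : str
        ``"accuracy"`` (default) or ``"balanced_accuracy"``.
    seed : int
        Random seed for stochastic families (random forest).
    n_trees : int
        Ensemble size for the random-forest family (default 50).
    feature_fraction : float
        Fraction of features sampled per tree in the forest (default 0.25).
    """

    family: Family = "svm_rbf"
    cost: float = 1.0
    gamma: float | str = "reciprocal_of_feature_count"
    scale: bool = True
    metric: str = "accuracy"
    seed: int = 0
    n_trees: int = 50
    feature_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise MalaniError("cost must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise MalaniError("numeric gamma must be positive")
        if self.family not in ("svm_rbf", "svm_linear", "random_forest", "logistic"):
            raise MalaniError(f"unknown classifier family {self.family!r}")
        if self.metric not in ("accuracy", "balanced_accuracy"):
            raise MalaniError(f"unknown metric {self.metric!r}")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)


@dataclass
class CVResult:
    """Per-fold and average cross-validated accuracy."""

    per_fold_accuracy: list[float]
    mean_accuracy: float

    @classmethod
    def from_folds(cls, per_fold: list[float]) -> "CVResult":
        return cls(per_fold_accuracy=list(per_fold), mean_accuracy=float(np.mean(per_fold)))


def forest_params(spec: ClassifierSpec) -> dict:
    """LightGBM parameter set for the bagged random-forest family.

    Small leaves and a low per-tree feature fraction suit the regime the
    pipeline lives in: tens of samples, hundreds of features, few of
    them relevant.
    """
    return dict(
        objective="binary",
        boosting="rf",
        num_iterations=spec.n_trees,
        bagging_fraction=0.8,
        bagging_freq=1,
        feature_fraction=spec.feature_fraction,
        min_data_in_leaf=3,
        num_leaves=31,
        verbosity=-1,
        seed=spec.seed,
        deterministic=True,
        num_threads=1,
        force_col_wise=True,
    )


def build_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn-style estimator described by ``spec``."""
    if spec.family == "svm_rbf":
        gamma = "auto" if spec.gamma == "reciprocal_of_feature_count" else spec.gamma
        return SVC(C=spec.cost, kernel="rbf", gamma=gamma)
    if spec.family == "svm_linear":
        return SVC(C=spec.cost, kernel="linear")
    if spec.family == "random_forest":
        p = forest_params(spec)
        return lgb.LGBMClassifier(
            boosting_type="rf",
            n_estimators=spec.n_trees,
            subsample=p["bagging_fraction"],
            subsample_freq=p["bagging_freq"],
            colsample_bytree=spec.feature_fraction,
            min_child_samples=p["min_data_in_leaf"],
            num_leaves=p["num_leaves"],
            random_state=spec.seed,
            n_jobs=1,
            verbose=-1,
        )
    if spec.family == "logistic":
        return LogisticRegression(max_iter=1000)
    raise MalaniError(f"unknown classifier family {spec.family!r}")


def _fold_score(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    if metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    accs = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(accs))


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    folds: FoldPlan,
    spec: ClassifierSpec,
) -> CVResult:
    """Cross-validated classification accuracy of a feature matrix.

    Parameters
    ----------
    features : ndarray of shape (F, S)
        One row per feature, one column per sample (the orientation every
        stage produces).
    labels : array of str
        Per-sample class labels.
    folds : FoldPlan
        Stratified fold assignment over the S samples.
    spec : ClassifierSpec
        Classifier configuration.
    """
    X = np.ascontiguousarray(np.asarray(features, dtype=float).T)  # S x F
    y = (np.asarray(labels, dtype=object) == "cancer").astype(int)
    if X.shape[0] != y.size or y.size != folds.n_samples:
        raise MalaniError("features, labels and folds disagree on sample count")
    if X.shape[1] < 1:
        raise MalaniError("need at least one feature")

    per_fold: list[float] = []
    params = forest_params(spec) if spec.family == "random_forest" else None
    svm_kernel = {"svm_rbf": "rbf", "svm_linear": "linear"}.get(spec.family)
    use_libsvm = _HAVE_LIBSVM and svm_kernel is not None
    for train, test in folds.splits():
        X_tr, X_te = X[train], X[test]
        y_tr, y_te = y[train], y[test]
        if len(np.unique(y_tr)) < 2:
            raise MalaniError("training fold contains a single class")
        if params is not None:
            # Native LightGBM call: same model as the sklearn wrapper,
            # much lower per-fit overhead (stage 1 fits thousands).
            booster = lgb.train(params, lgb.Dataset(X_tr, label=y_tr, params=params))
            y_pred = (booster.predict(X_te) > 0.5).astype(int)
        else:
            if spec.scale:
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0)
                sd[sd == 0] = 1.0
                X_tr = (X_tr - mu) / sd
                X_te = (X_te - mu) / sd
            if use_libsvm:
                y_pred = _libsvm_fit_predict(X_tr, y_tr, X_te, spec, svm_kernel)
            else:
                est = build_estimator(spec)
                est.fit(X_tr, y_tr)
                y_pred = est.predict(X_te)
        per_fold.append(_fold_score(y_te, y_pred, spec.metric))
    return CVResult.from_folds(per_fold)


def _libsvm_fit_predict(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    spec: ClassifierSpec,
    kernel: str,
) -> np.ndarray:
    """C-SVC fit/predict through the low-level libsvm bindings.

    Produces the same model as ``SVC(C=cost, kernel=..., gamma=...)`` —
    asserted against SVC in the test-suite — while skipping per-call
    estimator construction, which matters when stages fit tens of
    thousands of tiny models.
    """
    if spec.gamma == "reciprocal_of_feature_count":
        gamma = 1.0 / X_tr.shape[1]
    else:
        gamma = float(spec.gamma)
    model = _libsvm.fit(
        np.ascontiguousarray(X_tr, dtype=np.float64),
        y_tr.astype(np.float64),
        svm_type=0,
        kernel=kernel,
        gamma=gamma,
        C=spec.cost,
    )
    pred = _libsvm.predict(
        np.ascontiguousarray(X_te, dtype=np.float64),
        *model[:7],
        svm_type=0,
        kernel=kernel,
        gamma=gamma,
    )
    return pred.astype(int)
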