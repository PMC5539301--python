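"""scikit-learn-style estimators wrapping the three inference stages.

:class:`MalaniNetwork` is the main entry point: ``fit(X, y)`` on a
samples x genes matrix runs gene-wise selection, partner search and the
feature-selection vote, leaving the inferred network and all stage
artifacts as fitted attributes.  The stage estimators
(:class:`GeneWiseSelector`, :class:`PairPartnerSelector`) expose the
individual stages with the same conventions (``get_params`` /
``set_params``, trailing-underscore attributes, input validation), so
they compose with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .classifier import ClassifierSpec
from .data import ExpressionDataset, MalaniError, normalize_per_sample, stratified_folds
from .stage1 import select_theta
from .stage2 import top_partners
from .stage3 import infer_min

__all__ = ["GeneWiseSelector", "PairPartnerSelector", "MalaniNetwork"]


def _as_dataset(
    X: np.ndarray,
    y: Sequence,
    gene_names: Sequence[str] | None,
    normalize: bool,
) -> ExpressionDataset:
    X = check_array(X, dtype=float, ensure_min_samples=4)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise MalaniError("X and y disagree on sample count")
    if y.dtype.kind in "biu":
        labels = np.where(y.astype(int) == 1, "cancer", "normal").astype(object)
    else:
        labels = np.array([str(v).lower() for v in y], dtype=object)
    genes = (
        list(gene_names)
        if gene_names is not None
        else [f"G{i + 1:04d}" for i in range(X.shape[1])]
    )
    samples = [f"S{i + 1:04d}" for i in range(X.shape[0])]
    ds = ExpressionDataset(genes, samples, X.T, labels)
    return normalize_per_sample(ds) if normalize else ds


class GeneWiseSelector(BaseEstimator):
    """Stage 1 as a feature selector: keep the top fraction of genes.

    ``fit`` scores one product-feature model per gene by k-fold CV;
    ``transform`` restricts a matrix to the selected gene columns.
    """

    def __init__(
        self,
        theta_frac: float = 0.05,
        k_folds: int = 10,
        family: str = "random_forest",
        normalize: bool = True,
        seed: int = 0,
    ):
        self.theta_frac = theta_frac
        self.k_folds = k_folds
        self.family = family
        self.normalize = normalize
        self.seed = seed

    def fit(self, X, y, gene_names: Sequence[str] | None = None):
        ds = _as_dataset(X, y, gene_names, self.normalize)
        folds = stratified_folds(ds.labels, self.k_folds, seed=self.seed)
        spec = ClassifierSpec(family=self.family, seed=self.seed)
        theta, scores = select_theta(ds, folds, spec, frac=self.theta_frac)
        self.theta_ = theta
        self.scores_ = scores
        self.gene_names_ = list(ds.gene_ids)
        self.support_ = np.array([g in set(theta.genes) for g in ds.gene_ids])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise MalaniError("feature count changed between fit and transform")
        return X[:, self.support_]


class PairPartnerSelector(BaseEstimator):
    """Stage 2: find the best-classifying partners of the selected genes."""

    def __init__(
        self,
        n_partners: int = 10,
        k_folds: int = 10,
        family: str = "svm_rbf",
        normalize: bool = True,
        seed: int = 0,
    ):
        self.n_partners = n_partners
        self.k_folds = k_folds
        self.family = family
        self.normalize = normalize
        self.seed = seed

    def fit(self, X, y, theta=None, gene_names: Sequence[str] | None = None):
        if theta is None:
            raise MalaniError("PairPartnerSelector.fit requires theta")
        ds = _as_dataset(X, y, gene_names, self.normalize)
        folds = stratified_folds(ds.labels, self.k_folds, seed=self.seed)
        spec = ClassifierSpec(family=self.family, seed=self.seed)
        self.pair_list_ = top_partners(ds, theta, folds, spec, n=self.n_partners)
        return self


class MalaniNetwork(BaseEstimator):
    """The full three-stage network-inference estimator.

    Parameters mirror the pipeline defaults: top 5% gene-wise models,
    10 partners per selected gene, per-method top 10% vote lists and a
    3-of-5 majority.  Stage 1 uses a bagged random forest by default —
    gene-wise matrices carry few relevant rows among hundreds, a regime
    where axis-aligned ensembles excel — while the pair stages use the
    RBF-kernel SVM (cost 1, gamma = 1/n_features).

    Attributes (after ``fit``)
    --------------------------
    network_ : networkx.Graph
        The MALANI-inferred network; edges carry ensemble vote counts.
    theta_, gene_scores_, pair_list_, pair_matrix_, votes_ :
        Intermediate artifacts of the three stages.
    """

    def __init__(
        self,
        theta_frac: float = 0.05,
        n_partners: int = 10,
        top_frac: float = 0.1,
        min_votes: int = 3,
        k_folds: int = 10,
        stage1_family: str = "random_forest",
        pair_family: str = "svm_rbf",
        cost: float = 1.0,
        normalize: bool = True,
        seed: int = 0,
    ):
        self.theta_frac = theta_frac
        self.n_partners = n_partners
        self.top_frac = top_frac
        self.min_votes = min_votes
        self.k_folds = k_folds
        self.stage1_family = stage1_family
        self.pair_family = pair_family
        self.cost = cost
        self.normalize = normalize
        self.seed = seed

    def fit(self, X, y, gene_names: Sequence[str] | None = None):
        ds = _as_dataset(X, y, gene_names, self.normalize)
        self.dataset_ = ds
        folds = stratified_folds(ds.labels, self.k_folds, seed=self.seed)
        stage1_spec = ClassifierSpec(
            family=self.stage1_family, cost=self.cost, seed=self.seed
        )
        pair_spec = ClassifierSpec(
            family=self.pair_family, cost=self.cost, seed=self.seed
        )
        self.theta_, self.gene_scores_ = select_theta(
            ds, folds, stage1_spec, frac=self.theta_frac
        )
        self.pair_list_ = top_partners(
            ds, self.theta_, folds, pair_spec, n=self.n_partners
        )
        self.network_, self.votes_, self.pair_matrix_ = infer_min(
            ds,
            self.pair_list_,
            folds,
            pair_spec,
            min_votes=self.min_votes,
            top_frac=self.top_frac,
        )
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def edges_(self) -> list[tuple[str, str]]:
        check_is_fitted(self, "network_")
        return sorted(tuple(sorted(e)) for e in self.network_.edges)

    def score(self, X=None, y=None) -> float:
        """Mean CV accuracy of the final pair-product model on the fit data."""
        check_is_fitted(self, "network_")
        from .classifier import cv_accuracy
        from .stage3 import pair_product_matrix

        ds = self.dataset_
        if not self.edges_:
            return 0.5
        folds = stratified_folds(ds.labels, self.k_folds, seed=self.seed)
        spec = ClassifierSpec(family=self.pair_family, cost=self.cost, seed=self.seed)
        Q = pair_product_matrix(ds, self.edges_)
        return cv_accuracy(Q.values, ds.labels, folds, spec).mean_accuracy
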