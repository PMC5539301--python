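"""Stage 3: pair-product matrix, feature-selection ensemble, and the MIN.

The surviving pairs from stage 2 become rows of the matrix Q (one
per-sample product per pair).  Five feature-selection methods score every
row: information gain (IG), Relief-F, symmetrical uncertainty (SU),
SVM-recursive feature elimination (SVM_RFE) and individual accuracy (IA).
Each method nominates its top fraction of pairs; pairs nominated by at
least ``min_votes`` methods are agglomerated into the MALANI-inferred
network (MIN), an undirected graph whose edge attribute ``votes`` records
ensemble support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.svm import SVC

from .classifier import ClassifierSpec, cv_accuracy
from .data import ExpressionDataset, FoldPlan, MalaniError
from .stage2 import PairList

log = logging.getLogger(__name__)

__all__ = [
    "FS_METHODS",
    "PairMatrix",
    "FSVote",
    "pair_product_matrix",
    "score_features",
    "ensemble_select",
    "assemble_min",
    "information_gain",
    "symmetrical_uncertainty",
    "relieff_weights",
    "svm_rfe_ranking",
]

FS_METHODS = ("IG", "ReliefF", "SU", "SVM_RFE", "IA")


@dataclass
class PairMatrix:
    """Q: one row of per-sample products x_a * x_b per surviving pair."""

    pairs: list[tuple[str, str]]
    values: np.ndarray  # R x S

    @property
    def R(self) -> int:
        return len(self.pairs)


@dataclass
class FSVote:
    """Per-method rankings/selections and the resulting vote counts."""

    rankings: dict[str, np.ndarray]  # method -> scores (higher = better)
    selected: dict[str, list[int]]  # method -> selected row indices
    votes: np.ndarray  # per-pair vote count, 0..5


def pair_product_matrix(ds: ExpressionDataset, pairs: PairList | list) -> PairMatrix:
    pair_list = list(pairs)
    rows = np.empty((len(pair_list), ds.n_samples))
    for r, (a, b) in enumerate(pair_list):
        rows[r] = ds.values[ds.gene_index(a)] * ds.values[ds.gene_index(b)]
    return PairMatrix(pairs=pair_list, values=rows)


# ---------------------------------------------------------------------------
# Individual feature-selection scores
# ---------------------------------------------------------------------------


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize to (up to) n_bins equal-frequency bins; returns int codes."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information(codes: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Plug-in I(X;Y), H(X), H(Y) in bits from discrete codes."""
    xs = np.unique(codes)
    ys = np.unique(y)
    table = np.array([[np.sum((codes == xv) & (y == yv)) for yv in ys] for xv in xs])
    hx = _entropy(table.sum(axis=1))
    hy = _entropy(table.sum(axis=0))
    hxy = _entropy(table.ravel())
    return hx + hy - hxy, hx, hy


def information_gain(feature: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Mutual information (bits) between the discretized feature and the class."""
    mi, _, _ = _mutual_information(_equal_frequency_bins(feature, n_bins), y)
    return mi


def symmetrical_uncertainty(feature: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """SU = 2 I(X;Y) / (H(X) + H(Y)); 0 when either entropy is zero."""
    mi, hx, hy = _mutual_information(_equal_frequency_bins(feature, n_bins), y)
    if hx + hy <= 0:
        return 0.0
    return 2.0 * mi / (hx + hy)


def relieff_weights(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 10
) -> np.ndarray:
    """Relief-F feature weights.

    All samples are used (m = S); differences are computed on
    range-normalized features and neighbors found by Manhattan distance.
    For each sample the k nearest hits (same class) and k nearest misses
    raise/lower each feature's weight by its mean normalized difference.

    Parameters
    ----------
    X : ndarray of shape (S, F)
    y : ndarray of shape (S,), binary
    """
    S, F = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    Z = (X - X.min(axis=0)) / rng_span
    W = np.zeros(F)
    for i in range(S):
        diffs = np.abs(Z - Z[i])  # S x F
        dist = diffs.sum(axis=1)
        dist[i] = np.inf
        same = y == y[i]
        same[i] = False
        hits = np.where(same)[0]
        misses = np.where(~same & (np.arange(S) != i))[0]
        k_h = min(k_neighbors, hits.size)
        k_m = min(k_neighbors, misses.size)
        if k_h:
            nearest = hits[np.argsort(dist[hits], kind="stable")[:k_h]]
            W -= diffs[nearest].mean(axis=0) / S
        if k_m:
            nearest = misses[np.argsort(dist[misses], kind="stable")[:k_m]]
            W += diffs[nearest].mean(axis=0) / S
    return W


def svm_rfe_ranking(X: np.ndarray, y: np.ndarray, cost: float = 1.0) -> np.ndarray:
    """Recursive feature elimination with a linear SVM.

    Features are standardized once; each iteration drops the 10% of
    remaining features (at least one) with the smallest absolute weight,
    until a single feature remains.  Returns a score per feature equal to
    the elimination round (later-eliminated = higher; survivor highest).
    """
    S, F = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    remaining = list(range(F))
    score = np.zeros(F)
    round_no = 0
    while len(remaining) > 1:
        round_no += 1
        est = SVC(kernel="linear", C=cost)
        est.fit(Z[:, remaining], y)
        w = np.abs(est.coef_.ravel())
        n_drop = max(1, math.floor(0.1 * len(remaining)))
        drop_local = np.argsort(w, kind="stable")[:n_drop]
        for loc in sorted(drop_local, reverse=True):
            score[remaining[loc]] = round_no
            del remaining[loc]
    score[remaining[0]] = round_no + 1
    return score


def score_features(
    Q: PairMatrix,
    labels: np.ndarray,
    method: str,
    spec: ClassifierSpec,
    folds: FoldPlan | None = None,
    n_bins: int = 10,
    k_neighbors: int = 10,
) -> np.ndarray:
    """Score every pair row of Q with one feature-selection method.

    Higher scores are better for every method.
    """
    if Q.R == 0:
        raise MalaniError("Q is empty")
    y = (np.asarray(labels, dtype=object) == "cancer").astype(int)
    X = Q.values.T  # S x R
    if method == "IG":
        return np.array([information_gain(X[:, j], y, n_bins) for j in range(Q.R)])
    if method == "SU":
        return np.array(
            [symmetrical_uncertainty(X[:, j], y, n_bins) for j in range(Q.R)]
        )
    if method == "ReliefF":
        return relieff_weights(X, y, k_neighbors=k_neighbors)
    if method == "SVM_RFE":
        return svm_rfe_ranking(X, y, cost=spec.cost)
    if method == "IA":
        if folds is None:
            raise MalaniError("IA scoring requires a fold plan")
        return np.array(
            [
                cv_accuracy(Q.values[j : j + 1], labels, folds, spec).mean_accuracy
                for j in range(Q.R)
            ]
        )
    raise MalaniError(f"unknown feature-selection method {method!r}")


# ---------------------------------------------------------------------------
# Ensemble voting and network assembly
# ---------------------------------------------------------------------------


def ensemble_select(
    rankings: dict[str, np.ndarray],
    R: int,
    min_votes: int = 3,
    top_frac: float = 0.1,
) -> FSVote:
    """Vote pairs through the per-method top lists.

    Each method selects its top ``ceil(top_frac * R)`` pairs (ties broken
    by pair order); pairs appearing in at least ``min_votes`` of the
    selections win.
    """
    if not (1 <= min_votes <= 5):
        raise MalaniError("min_votes must lie in 1..5")
    if not (0.0 < top_frac <= 1.0):
        raise MalaniError("top_frac must lie in (0, 1]")
    n_top = math.ceil(top_frac * R)
    votes = np.zeros(R, dtype=int)
    selected: dict[str, list[int]] = {}
    for method, scores in rankings.items():
        if len(scores) != R:
            raise MalaniError(f"method {method} scored {len(scores)} of {R} pairs")
        order = sorted(range(R), key=lambda j: (-scores[j], j))
        top = order[:n_top]
        selected[method] = top
        votes[top] += 1
    return FSVote(rankings=dict(rankings), selected=selected, votes=votes)


def assemble_min(
    pairs: list[tuple[str, str]],
    votes: np.ndarray,
    min_votes: int = 3,
) -> nx.Graph:
    """Agglomerate winning pairs into the MALANI-inferred network."""
    g: nx.Graph = nx.Graph()
    for (a, b), v in zip(pairs, votes):
        if v >= min_votes:
            g.add_edge(a, b, votes=int(v))
    return g


def infer_min(
    ds: ExpressionDataset,
    pair_list: PairList,
    folds: FoldPlan,
    spec: ClassifierSpec,
    min_votes: int = 3,
    top_frac: float = 0.1,
) -> tuple[nx.Graph, FSVote, PairMatrix]:
    """Full stage 3: build Q, score with all five methods, vote, assemble."""
    Q = pair_product_matrix(ds, pair_list)
    rankings = {
        m: score_features(Q, ds.labels, m, spec, folds=folds) for m in FS_METHODS
    }
    vote = ensemble_select(rankings, Q.R, min_votes=min_votes, top_frac=top_frac)
    g = assemble_min(Q.pairs, vote.votes, min_votes=min_votes)
    log.info("stage3: %d of %d pairs selected into the MIN", g.number_of_edges(), Q.R)
    return g, vote, Q
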