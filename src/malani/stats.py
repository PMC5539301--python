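"""Evaluation statistics: permutation tests, per-gene p-values, multiple
testing, hypergeometric enrichment, the hub/class-II association test and
the model-count formula.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotate import GeneClassLabels, find_hubs
from .classifier import ClassifierSpec, cv_accuracy
from .data import (
    ExpressionDataset,
    GeneSetCollection,
    MalaniError,
    stratified_folds,
)

log = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "EnrichmentResult",
    "permutation_test",
    "screening_model_statistic",
    "per_gene_pvalues",
    "adjust_pvalues",
    "hypergeom_enrich",
    "fisher_hub_class2",
    "model_count",
    "monte_carlo_ci",
]


@dataclass
class PermutationResult:
    observed_stat: float
    permuted_stats: list[float]
    alpha: float  # Monte-Carlo p: #{|perm| >= |obs|} / M
    ci_low: float
    ci_high: float

    @property
    def M(self) -> int:
        return len(self.permuted_stats)


@dataclass
class EnrichmentResult:
    category: str
    n: int  # query size
    m: int  # reference size
    j: int  # category size in reference
    k_obs: int  # overlap
    k_expected: float  # (n/m) * j
    ratio: float  # k_obs / k_expected
    p_raw: float  # hypergeometric upper tail P(X >= k_obs)
    p_adj: float  # Bonferroni across categories
    enriched: bool  # ratio > 1
    passes_filter: bool = False


def monte_carlo_ci(alpha: float, M: int) -> tuple[float, float]:
    """95% CI around a Monte-Carlo p-value: alpha +/- 1.96*sqrt(alpha(1-alpha)/M)."""
    half = 1.96 * np.sqrt(alpha * (1.0 - alpha) / M)
    return max(0.0, alpha - half), min(1.0, alpha + half)


def permutation_test(
    ds: ExpressionDataset,
    statistic: Callable[[ExpressionDataset], float],
    M: int = 20,
    seed: int = 0,
) -> PermutationResult:
    """Monte-Carlo permutation test of a classification statistic.

    The statistic (typically the cross-validated accuracy of the final
    selected model) is computed on the true labels, then on ``M``
    independent label permutations.  The observed p-value is the plain
    #{|permuted| >= |observed|} / M estimator — no smoothing, so an
    alpha of exactly zero is possible and collapses the CI to [0, 0].
    """
    if M < 1:
        raise MalaniError("M must be >= 1")
    obs = float(statistic(ds))
    if not np.isfinite(obs):
        raise MalaniError("statistic returned a non-finite value")
    rng = np.random.default_rng(seed)
    permuted: list[float] = []
    for _ in range(M):
        shuffled = ds.labels.copy()
        rng.shuffle(shuffled)
        ds_perm = ExpressionDataset(
            gene_ids=ds.gene_ids,
            sample_ids=ds.sample_ids,
            values=ds.values,
            labels=shuffled,
            normalized=ds.normalized,
        )
        val = float(statistic(ds_perm))
        if not np.isfinite(val):
            raise MalaniError("statistic returned a non-finite value")
        permuted.append(val)
    alpha = float(np.mean([abs(p) >= abs(obs) for p in permuted]))
    lo, hi = monte_carlo_ci(alpha, M)
    return PermutationResult(obs, permuted, alpha, lo, hi)


def selected_model_statistic(
    pairs: Sequence[tuple[str, str]],
    spec: ClassifierSpec,
    k: int = 10,
    fold_seed: int = 0,
) -> Callable[[ExpressionDataset], float]:
    """Statistic factory: mean CV accuracy of the pair-product model.

    The returned callable rebuilds stratified folds from the (possibly
    permuted) labels it receives, so each permutation is evaluated under
    its own class-balanced fold plan.
    """
    from .stage3 import pair_product_matrix

    def stat(ds: ExpressionDataset) -> float:
        folds = stratified_folds(ds.labels, k, seed=fold_seed)
        Q = pair_product_matrix(ds, list(pairs))
        return cv_accuracy(Q.values, ds.labels, folds, spec).mean_accuracy

    return stat


def screening_model_statistic(
    spec: ClassifierSpec,
    theta_frac: float = 0.05,
    n_partners: int = 10,
    top_frac: float = 0.1,
    k: int = 10,
    fold_seed: int = 0,
) -> Callable[[ExpressionDataset], float]:
    """Statistic factory: CV accuracy of a re-selected pair-product model.

    A valid permutation test of an adaptive pipeline must repeat the
    *selection* under every permuted labelling, not just re-evaluate the
    model selected on the true labels.  Re-running the full three-stage
    funnel per permutation is far too expensive, so this statistic runs
    a fast surrogate of it, nested inside cross-validation, on whatever
    labels it is handed.  Per fold, using training samples only:

    1. score every gene pair by the absolute pooled-t statistic of its
       per-sample product (vectorised over all G^2 pairs);
    2. anchors = top ``ceil(theta_frac*G)`` genes by their best pair t;
    3. per anchor keep the ``n_partners`` best partners, then keep the
       top ``ceil(top_frac * R)`` of the surviving pairs;
    4. fit the classifier on the selected product rows of the training
       fold and score the held-out portion.

    Selection never sees the test fold, so the statistic is an honest
    generalisation estimate, and because the identical adaptive
    procedure is applied to observed and permuted labels the Monte-Carlo
    p-value is calibrated under the no-association null.  Memory grows
    as G^2 x S; intended for desk-scale matrices.
    """

    def stat(ds: ExpressionDataset) -> float:
        X = ds.values
        G, S = X.shape
        y = ds.y
        n_anchor = int(np.ceil(theta_frac * G))
        PF = (X[:, None, :] * X[None, :, :]).reshape(G * G, S)
        PF2 = PF * PF
        folds = stratified_folds(ds.labels, k, seed=fold_seed)
        accs = []
        for train, test in folds.splits():
            t = _pair_product_tstats(PF, PF2, y, train, G)
            kept = _screen_pairs(t, n_anchor, n_partners, top_frac)
            rows = PF[[a * G + b for a, b in kept]]
            X_tr = rows[:, train].T
            X_te = rows[:, test].T
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            from .classifier import build_estimator

            est = build_estimator(spec)
            est.fit((X_tr - mu) / sd, y[train])
            pred = est.predict((X_te - mu) / sd)
            accs.append(float(np.mean(pred == y[test])))
        return float(np.mean(accs))

    return stat


def _pair_product_tstats(
    PF: np.ndarray, PF2: np.ndarray, y: np.ndarray, train: np.ndarray, G: int
) -> np.ndarray:
    """|pooled t| of every pair product over the training samples."""
    mask1 = np.zeros(PF.shape[1])
    mask0 = np.zeros(PF.shape[1])
    mask1[train[y[train] == 1]] = 1.0
    mask0[train[y[train] == 0]] = 1.0
    n1, n0 = mask1.sum(), mask0.sum()
    s1, s0 = PF @ mask1, PF @ mask0
    q1, q0 = PF2 @ mask1, PF2 @ mask0
    m1, m0 = s1 / n1, s0 / n0
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v0 = (q0 - n0 * m0**2) / (n0 - 1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    t[~np.isfinite(t)] = 0.0
    t = t.reshape(G, G)
    np.fill_diagonal(t, -np.inf)
    return t


def _screen_pairs(
    t: np.ndarray, n_anchor: int, n_partners: int, top_frac: float
) -> list[tuple[int, int]]:
    """Anchor scan -> partner scan -> top-fraction cut on a |t| matrix."""
    anchors = np.argsort(-t.max(axis=1), kind="stable")[:n_anchor]
    pairs: dict[tuple[int, int], float] = {}
    for a in anchors:
        partners = np.argsort(-t[a], kind="stable")[:n_partners]
        for b in partners:
            key = (min(int(a), int(b)), max(int(a), int(b)))
            score = float(t[a, b])
            if score > pairs.get(key, -np.inf):
                pairs[key] = score
    keys = list(pairs)
    n_keep = max(1, int(np.ceil(top_frac * len(keys))))
    order = sorted(range(len(keys)), key=lambda i: (-pairs[keys[i]], i))
    return [keys[i] for i in order[:n_keep]]


def per_gene_pvalues(ds: ExpressionDataset, welch: bool = False) -> dict[str, float]:
    """Two-sided two-sample t-test p-value per gene (pooled variance).

    Welch's unequal-variance form is available by flag.  Genes with zero
    variance in both classes get p = 1 with a warning.
    """
    is_cancer = ds.labels == "cancer"
    xc = ds.values[:, is_cancer]
    xn = ds.values[:, ~is_cancer]
    if xc.shape[1] < 2 or xn.shape[1] < 2:
        raise MalaniError("each class needs at least two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(xc, xn, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero pooled variance; p set to 1"
        )
        p[degenerate] = 1.0
    return dict(zip(ds.gene_ids, p))


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise MalaniError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise MalaniError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def hypergeom_enrich(
    query: set[str],
    sets: GeneSetCollection,
    mode: str = "min",
    top_n: int = 10,
    min_genes_min: int = 3,
    min_genes_piemin: int = 5,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query set per category.

    ``p_raw`` is the upper tail P(X >= k) of drawing ``n`` genes from a
    reference of ``m`` containing ``j`` category members; Bonferroni
    correction is applied across categories.  ``mode='min'`` marks the
    top ``top_n`` categories by raw p with at least 3 query genes as
    passing; ``mode='piemin'`` marks categories with adjusted p < 0.05
    and at least 5 query genes.
    """
    if len(sets) == 0:
        raise MalaniError("empty gene-set collection")
    if mode not in ("min", "piemin"):
        raise MalaniError("mode must be 'min' or 'piemin'")
    n = len(query)
    m = sets.reference_size
    n_cat = len(sets)
    results: list[EnrichmentResult] = []
    for name, members in sets.categories.items():
        j = len(members)
        k_obs = len(query & members)
        k_exp = (n / m) * j
        p_raw = float(sps.hypergeom.sf(k_obs - 1, m, j, n))
        results.append(
            EnrichmentResult(
                category=name,
                n=n,
                m=m,
                j=j,
                k_obs=k_obs,
                k_expected=k_exp,
                ratio=(k_obs / k_exp) if k_exp > 0 else float("nan"),
                p_raw=p_raw,
                p_adj=min(1.0, p_raw * n_cat),
                enriched=k_obs > k_exp,
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.category))
    if mode == "min":
        eligible = [r for r in results if r.k_obs >= min_genes_min]
        for r in eligible[:top_n]:
            r.passes_filter = True
    else:
        for r in results:
            r.passes_filter = r.p_adj < alpha and r.k_obs >= min_genes_piemin
    return results


def fisher_hub_class2(
    net: nx.Graph,
    labels: GeneClassLabels,
    background_size: int,
    min_connectivity: int = 6,
) -> tuple[np.ndarray, float]:
    """Fisher's exact test: do hubs preferentially connect to class II genes?

    The 2x2 table crosses hub-adjacency (being a neighbor of a hub in the
    network) with class-II membership over a background of
    ``background_size`` genes; genes outside the network count as neither.
    """
    hubs = find_hubs(net, min_connectivity)
    hub_adjacent = {v for h in hubs for v in net.neighbors(h)}
    class2 = labels.genes_with("class_II")
    a = len(hub_adjacent & class2)
    b = len(class2 - hub_adjacent)
    c = len(hub_adjacent - class2)
    d = background_size - a - b - c
    if d < 0:
        raise MalaniError(
            "background_size smaller than the observed gene universe"
        )
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def model_count(G: int, k: int) -> float:
    """Number of classifier fits in the two scanning stages: k*G*(1 + (G-1)/20).

    The first term counts the G gene-wise models per fold; the second the
    pair models for the top 5% of genes each paired with G-1 partners
    (5% * (G-1) * G = G*(G-1)/20).
    """
    if G < 1 or k < 1:
        raise MalaniError("G and k must be >= 1")
    return k * G * (1.0 + (G - 1) / 20.0)
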