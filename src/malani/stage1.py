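"""Stage 1: gene-wise product-feature models and top-5% gene selection.

For each gene *i* the stage builds the (G-1) x S matrix whose rows are the
per-sample products x_i(s) * x_j(s) for every other gene j, scores it by
cross-validated classification accuracy, ranks all genes by that score and
keeps the top fraction (default 5%) as the selected gene set Theta.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierSpec, CVResult, cv_accuracy
from .data import ExpressionDataset, FoldPlan, MalaniError

log = logging.getLogger(__name__)

__all__ = ["GeneWiseScore", "ThetaSet", "genewise_products", "theta_size", "select_theta"]


@dataclass
class GeneWiseScore:
    gene: str
    cv: CVResult
    rank: int  # 1 = best mean accuracy


@dataclass
class ThetaSet:
    """The selected gene set Theta (ordered best-first)."""

    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)


def genewise_products(ds: ExpressionDataset, gene: str) -> np.ndarray:
    """Per-sample products of one gene with every other gene.

    Returns a (G-1) x S matrix; row order follows the dataset's gene
    order with ``gene`` removed.
    """
    i = ds.gene_index(gene)
    products = ds.values * ds.values[i]
    return np.delete(products, i, axis=0)


def theta_size(n_genes: int, frac: float = 0.05) -> int:
    """Number of genes kept: ceil(frac * G), never zero for frac > 0."""
    if not (0.0 < frac <= 1.0):
        raise MalaniError("frac must lie in (0, 1]")
    return math.ceil(frac * n_genes)


def select_theta(
    ds: ExpressionDataset,
    folds: FoldPlan,
    spec: ClassifierSpec,
    frac: float = 0.05,
) -> tuple[ThetaSet, list[GeneWiseScore]]:
    """Score every gene-wise model and keep the top ``frac`` as Theta.

    Ties in mean accuracy are broken by dataset gene order (earlier gene
    wins) so the selection is deterministic.
    """
    if not ds.normalized:
        raise MalaniError("dataset must be normalized before stage 1")
    n_keep = theta_size(ds.n_genes, frac)
    results: list[CVResult] = []
    for idx, gene in enumerate(ds.gene_ids):
        cv = cv_accuracy(genewise_products(ds, gene), ds.labels, folds, spec)
        results.append(cv)
        if (idx + 1) % 100 == 0:
            log.info("stage1: scored %d/%d gene-wise models", idx + 1, ds.n_genes)

    order = sorted(
        range(ds.n_genes), key=lambda i: (-results[i].mean_accuracy, i)
    )
    scores = [
        GeneWiseScore(gene=ds.gene_ids[i], cv=results[i], rank=r + 1)
        for r, i in enumerate(order)
    ]
    theta = ThetaSet(genes=[ds.gene_ids[i] for i in order[:n_keep]])
    return theta, scores
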