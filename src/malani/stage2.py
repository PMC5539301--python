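"""Stage 2: two-gene models anchored on the selected gene set Theta.

Each Theta gene is paired with every other gene in the dataset; a
two-feature classifier (the two expression rows) is cross-validated for
every pairing and the top ``n`` partners per anchor are kept.  Symmetric
duplicates (a selected b and b selected a) are merged, so the resulting
candidate list is a set of unique unordered pairs with provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierSpec, CVResult, cv_accuracy
from .data import ExpressionDataset, FoldPlan, MalaniError
from .stage1 import ThetaSet

log = logging.getLogger(__name__)

__all__ = ["PairScore", "PairList", "pair_features", "top_partners"]


@dataclass
class PairScore:
    gene_theta: str
    partner: str
    cv: CVResult
    kept: bool = False


@dataclass
class PairList:
    """Unique unordered candidate pairs, with the anchors that produced them."""

    pairs: list[tuple[str, str]]
    anchors: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    scores: list[PairScore] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def pair_features(ds: ExpressionDataset, a: str, b: str) -> np.ndarray:
    """The 2 x S feature matrix of a gene pair (row 1 = a, row 2 = b)."""
    if a == b:
        raise MalaniError("pair members must be distinct")
    return ds.values[[ds.gene_index(a), ds.gene_index(b)]]


def top_partners(
    ds: ExpressionDataset,
    theta: ThetaSet,
    folds: FoldPlan,
    spec: ClassifierSpec,
    n: int = 10,
) -> PairList:
    """Keep the ``n`` best-classifying partners for every Theta gene.

    Partners range over all other genes (including other Theta genes).
    Ties in mean accuracy are broken by dataset gene order.  The merged
    pair list is ordered by anchor (Theta order), then partner rank.
    """
    if n < 1:
        raise MalaniError("n must be >= 1")
    if theta.size == 0:
        raise MalaniError("theta is empty")

    order_index = {g: i for i, g in enumerate(ds.gene_ids)}
    pairs: list[tuple[str, str]] = []
    anchors: dict[tuple[str, str], list[str]] = {}
    all_scores: list[PairScore] = []

    for a_num, anchor in enumerate(theta):
        i = ds.gene_index(anchor)
        partner_scores: list[PairScore] = []
        for j, partner in enumerate(ds.gene_ids):
            if j == i:
                continue
            cv = cv_accuracy(ds.values[[i, j]], ds.labels, folds, spec)
            partner_scores.append(PairScore(anchor, partner, cv))
        partner_scores.sort(
            key=lambda s: (-s.cv.mean_accuracy, order_index[s.partner])
        )
        for s in partner_scores[:n]:
            s.kept = True
            key = tuple(sorted((s.gene_theta, s.partner), key=order_index.__getitem__))
            if key not in anchors:
                pairs.append(key)
                anchors[key] = []
            anchors[key].append(anchor)
        all_scores.extend(partner_scores)
        log.info("stage2: anchor %d/%d (%s) done", a_num + 1, theta.size, anchor)

    return PairList(pairs=pairs, anchors=anchors, scores=all_scores)
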