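"""Classify network genes, find hubs, and compare networks across cancers.

Class I cancer genes are differentially expressed (fold-change criterion)
and/or mutated; class II genes sit inside the inferred network while
being neither — the "signal linker" candidates the pipeline exists to
find.  Genes absent from the network are labelled ``outside_network``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionDataset, MalaniError, MutationTable

log = logging.getLogger(__name__)

__all__ = [
    "DEStatus",
    "GeneClassLabels",
    "fold_change_status",
    "classify_genes",
    "find_hubs",
    "cross_cancer_union",
]

PSEUDOCOUNT = 1e-12


@dataclass
class DEStatus:
    """Per-gene differential-expression status at a fold-change threshold."""

    table: pd.DataFrame  # index: gene; columns: fold_change, status
    threshold: float

    def status_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "status"])

    @property
    def not_de_genes(self) -> set[str]:
        return set(self.table.index[self.table["status"] == "not_de"])


@dataclass
class GeneClassLabels:
    """Per-gene class labels plus summary counts."""

    labels: dict[str, str]  # gene -> class_I | class_II | outside_network
    summary: dict[str, float]

    def genes_with(self, label: str) -> set[str]:
        return {g for g, l in self.labels.items() if l == label}


def fold_change_status(ds: ExpressionDataset, threshold: float = 1.5) -> DEStatus:
    """Label genes up/down/not_de by the ratio of class means.

    ``up`` means the cancer mean exceeds ``threshold`` times the normal
    mean; ``down`` the reverse.  Means are taken on the matrix as given
    (normalized intensities in the standard pipeline).  Zero class means
    are nudged by a pseudocount and flagged with a warning.
    """
    if threshold <= 0:
        raise MalaniError("threshold must be positive")
    is_cancer = ds.labels == "cancer"
    mean_c = ds.values[:, is_cancer].mean(axis=1)
    mean_n = ds.values[:, ~is_cancer].mean(axis=1)
    zero = (mean_c <= 0) | (mean_n <= 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) have a zero class mean; using pseudocount"
        )
        mean_c = np.maximum(mean_c, PSEUDOCOUNT)
        mean_n = np.maximum(mean_n, PSEUDOCOUNT)
    fc = mean_c / mean_n
    status = np.where(fc > threshold, "up", np.where(1.0 / fc > threshold, "down", "not_de"))
    table = pd.DataFrame({"fold_change": fc, "status": status}, index=ds.gene_ids)
    return DEStatus(table=table, threshold=threshold)


def classify_genes(
    min_net: nx.Graph,
    de: DEStatus,
    muts: MutationTable | None = None,
) -> GeneClassLabels:
    """Partition all genes into class_I / class_II / outside_network.

    A gene inside the network is class II when it is not differentially
    expressed and carries no mutation record; otherwise it is class I.
    """
    mutated = muts.genes if muts is not None else set()
    labels: dict[str, str] = {}
    for gene in de.table.index:
        if gene not in min_net:
            labels[gene] = "outside_network"
        elif de.status_of(gene) == "not_de" and gene not in mutated:
            labels[gene] = "class_II"
        else:
            labels[gene] = "class_I"
    n1 = sum(1 for l in labels.values() if l == "class_I")
    n2 = sum(1 for l in labels.values() if l == "class_II")
    not_de_total = len(de.not_de_genes)
    summary = {
        "n_class_I": n1,
        "n_class_II": n2,
        "n_outside_network": len(labels) - n1 - n2,
        "class_II_fraction_of_not_de": (n2 / not_de_total) if not_de_total else 0.0,
    }
    return GeneClassLabels(labels=labels, summary=summary)


def find_hubs(min_net: nx.Graph, min_connectivity: int = 6) -> set[str]:
    """Genes whose network connectivity is at least ``min_connectivity``.

    The default 6 implements the "connectivity higher than 5" hub rule.
    """
    return {n for n, d in min_net.degree if d >= min_connectivity}


def cross_cancer_union(
    mins: dict[str, nx.Graph],
) -> tuple[nx.Graph, pd.DataFrame, pd.DataFrame]:
    """Union several inferred networks and tabulate sharing.

    Returns the union graph (with per-node/edge ``present_in`` lists) and
    two tables: genes and edges with the count of networks containing
    them.
    """
    if not mins:
        raise MalaniError("need at least one network")
    union: nx.Graph = nx.Graph()
    for name, g in mins.items():
        for n in g.nodes:
            if n not in union:
                union.add_node(n, present_in=[])
            union.nodes[n]["present_in"].append(name)
        for a, b in g.edges:
            if not union.has_edge(a, b):
                union.add_edge(a, b, present_in=[])
            union.edges[a, b]["present_in"].append(name)
    genes = pd.DataFrame(
        [
            {"gene": n, "n_networks": len(d["present_in"]),
             "networks": ",".join(sorted(d["present_in"]))}
            for n, d in union.nodes(data=True)
        ]
    ).sort_values(["n_networks", "gene"], ascending=[False, True], ignore_index=True)
    edges = pd.DataFrame(
        [
            {"source": min(a, b), "target": max(a, b),
             "n_networks": len(d["present_in"]),
             "networks": ",".join(sorted(d["present_in"]))}
            for a, b, d in union.edges(data=True)
        ]
    ).sort_values(
        ["n_networks", "source", "target"], ascending=[False, True, True],
        ignore_index=True,
    )
    return union, genes, edges


def shared_at_least(table: pd.DataFrame, t: int) -> pd.DataFrame:
    """Rows present in at least ``t`` networks."""
    return table[table["n_networks"] >= t].reset_index(drop=True)
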