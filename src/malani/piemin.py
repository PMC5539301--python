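"""Expand an inferred network along shortest protein-protein paths.

For every gene pair (edge) of the MIN, the single shortest path through
the PPI network is computed (the graph is unweighted, so Dijkstra's
algorithm reduces to breadth-first search; among equal-length paths the
lexicographically smallest node sequence is kept for determinism).  The
union of all pair endpoints and path nodes/edges is the PIE-MIN; each
node's ``frequency`` counts the shortest paths passing through it.

The mutation landscape summarizes, over PIE-MIN genes: per-mutation-type
gene counts, cumulative PPI-neighbor counts, genes carrying at least
three distinct mutation types, and (optionally) a p-value-filtered
candidate subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotate import DEStatus, GeneClassLabels
from .data import MutationTable, PPINetwork

log = logging.getLogger(__name__)

__all__ = [
    "PathRecord",
    "PIEMIN",
    "LandscapeSummary",
    "shortest_path",
    "build_pie_min",
    "mutation_landscape",
]


@dataclass
class PathRecord:
    pair: tuple[str, str]
    path: list[str]  # node sequence a..b when found, else []
    length: int  # interior node count (found paths only)
    status: str  # found | endpoint_missing | disconnected


@dataclass
class PIEMIN:
    graph: nx.Graph
    node_frequency: dict[str, int]
    records: list[PathRecord] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class LandscapeSummary:
    type_gene_counts: dict[str, int]
    cumulative_neighbors: dict[str, int]
    multi_type_genes: list[str]
    node_labels: dict[str, str]
    subnetwork: nx.Graph | None = None
    pvalue_q3: float | None = None


def shortest_path(ppi: PPINetwork, a: str, b: str) -> PathRecord:
    """Single shortest PPI path between two genes.

    Among equal-length shortest paths the lexicographically smallest
    node sequence is returned, obtained by walking from ``a`` toward
    ``b`` and always taking the smallest neighbor that still lies on a
    shortest path.  Missing endpoints and disconnected pairs are encoded
    in the record status rather than raised.
    """
    g = ppi.graph
    if a not in g or b not in g:
        return PathRecord((a, b), [], 0, "endpoint_missing")
    if a == b:
        return PathRecord((a, b), [a], 0, "found")
    # distances from b: greedy descent then yields the lexicographically
    # smallest shortest a->b sequence
    dist = nx.single_source_shortest_path_length(g, b)
    if a not in dist:
        return PathRecord((a, b), [], 0, "disconnected")
    path = [a]
    current = a
    while current != b:
        d = dist[current]
        nxt = min(v for v in g.neighbors(current) if dist.get(v, np.inf) == d - 1)
        path.append(nxt)
        current = nxt
    return PathRecord((a, b), path, max(len(path) - 2, 0), "found")


def build_pie_min(
    min_net: nx.Graph,
    ppi: PPINetwork,
    count_endpoints: bool = False,
) -> tuple[PIEMIN, list[PathRecord]]:
    """Union the shortest PPI paths of every MIN edge into the PIE-MIN.

    ``node_frequency`` counts, per node, the number of shortest paths
    passing through it; by default only interior (pass-through) nodes are
    counted, with endpoints switchable via ``count_endpoints``.  Pairs
    whose path cannot be found are recorded and skipped.
    """
    g: nx.Graph = nx.Graph()
    freq: dict[str, int] = {}
    records: list[PathRecord] = []
    for a, b in sorted(tuple(sorted(e)) for e in min_net.edges):
        rec = shortest_path(ppi, a, b)
        records.append(rec)
        if rec.status != "found":
            log.warning("no PPI path for pair (%s, %s): %s", a, b, rec.status)
            continue
        nx.add_path(g, rec.path)
        counted = rec.path if count_endpoints else rec.path[1:-1]
        for node in counted:
            freq[node] = freq.get(node, 0) + 1
    for node in g.nodes:
        freq.setdefault(node, 0)
    return PIEMIN(graph=g, node_frequency=freq, records=records), records


def mutation_landscape(
    pm: PIEMIN,
    muts: MutationTable,
    ppi: PPINetwork,
    labels: GeneClassLabels | None = None,
    de: DEStatus | None = None,
    pvalues: dict[str, float] | None = None,
    multi_type_min: int = 3,
) -> LandscapeSummary:
    """Summarize the mutation landscape of a PIE-MIN.

    Per mutation type: the count of PIE-MIN genes carrying it and the
    cumulative number of their direct PPI neighbors (sum of PPI degrees,
    multiplicity kept).  ``multi_type_genes`` carry at least
    ``multi_type_min`` distinct types.  When per-gene p-values are given,
    the candidate genes (class II or differentially expressed, inside
    the PIE-MIN) with p-values above the candidates' third quartile
    induce the reported subnetwork.
    """
    genes = pm.genes
    in_pm = muts.records[muts.records["gene"].isin(genes)]
    type_counts: dict[str, int] = {}
    cum_neighbors: dict[str, int] = {}
    for mtype, group in in_pm.groupby("mutation_type"):
        gene_list = sorted(set(group["gene"]))
        type_counts[str(mtype)] = len(gene_list)
        cum_neighbors[str(mtype)] = int(sum(ppi.degree(g) for g in gene_list))
    per_gene = in_pm.groupby("gene")["mutation_type"].nunique()
    multi = sorted(per_gene.index[per_gene >= multi_type_min])

    node_labels: dict[str, str] = {}
    if labels is not None:
        node_labels = {g: labels.labels.get(g, "outside_network") for g in genes}

    subnetwork = None
    q3 = None
    if pvalues is not None and labels is not None and de is not None:
        candidates = sorted(
            g
            for g in genes
            if g in pvalues
            and (
                labels.labels.get(g) == "class_II"
                or (g in de.table.index and de.status_of(g) != "not_de")
            )
        )
        if candidates:
            ps = np.array([pvalues[g] for g in candidates])
            q3 = float(np.quantile(ps, 0.75))
            keep = [g for g, p in zip(candidates, ps) if p > q3]
            subnetwork = pm.graph.subgraph(keep).copy()

    return LandscapeSummary(
        type_gene_counts=type_counts,
        cumulative_neighbors=cum_neighbors,
        multi_type_genes=list(multi),
        node_labels=node_labels,
        subnetwork=subnetwork,
        pvalue_q3=q3,
    )
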