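"""Core data containers and file I/O.

Everything downstream operates on a gene x sample expression matrix with
binary cancer/normal labels, optionally accompanied by an undirected
protein-protein interaction (PPI) network, a gene-set collection (GMT) and
a mutation catalogue.  All file formats are plain text (TSV / SIF / GMT /
GraphML) so datasets round-trip losslessly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_LABELS = ("cancer", "normal")

#: Default mutation-type vocabulary for mutation catalogues.
MUTATION_TYPES = (
    "missense",
    "silent",
    "nonsense",
    "splicing",
    "frameshift_insertion",
    "frameshift_deletion",
    "amplified",
    "intronic",
    "in_frame_indel",
    "other",
)


class MalaniError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MalaniError):
    """A file could not be parsed or failed validation."""


class ConsistencyError(MalaniError):
    """Two inputs that must agree (e.g. matrix and labels) do not."""


# ---------------------------------------------------------------------------
# Expression dataset
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A gene x sample intensity matrix with binary sample labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique, ordered gene identifiers (rows).
    sample_ids : list of str
        Unique, ordered sample identifiers (columns).
    values : ndarray of shape (G, S)
        Non-negative intensities (arbitrary units).
    labels : ndarray of str
        Per-sample class, each either ``"cancer"`` or ``"normal"``.
    normalized : bool
        True once every sample column has been scaled to sum to one.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ParseError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ParseError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConsistencyError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError("expression values must be finite")
        if np.any(self.values < 0):
            raise ParseError("expression values must be non-negative")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ParseError(
                f"labels must be one of {VALID_LABELS}; offending value(s): {sorted(bad)}"
            )
        if len(set(self.labels)) < 2:
            raise ConsistencyError("both classes (cancer and normal) must be present")
        if self.normalized:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ConsistencyError("normalized flag set but column sums differ from 1")

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def y(self) -> np.ndarray:
        """Labels encoded as integers (cancer=1, normal=0)."""
        return (self.labels == "cancer").astype(int)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def normalize_per_sample(ds: ExpressionDataset) -> ExpressionDataset:
    """Divide each sample column by its total intensity.

    Column sums become 1, making intensities comparable across arrays while
    preserving within-sample expression ratios.  Idempotent.
    """
    sums = ds.values.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        names = [ds.sample_ids[i] for i in zero]
        raise MalaniError(f"cannot normalize: zero total intensity in sample(s) {names}")
    return ExpressionDataset(
        gene_ids=ds.gene_ids,
        sample_ids=ds.sample_ids,
        values=ds.values / sums,
        labels=ds.labels.copy(),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """A class-stratified assignment of samples to k portions.

    ``assignment[s]`` is the portion index (0-based, 0..k-1) of sample s.
    Fold ``f`` uses portion ``(f - 1) mod k`` as its test set, i.e. the
    first training fold holds out the last portion, the second holds out
    the first, and so on around the ring.
    """

    k: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise MalaniError("fold assignment indices must lie in 0..k-1")

    @property
    def n_samples(self) -> int:
        return self.assignment.size

    def test_portion(self, fold: int) -> int:
        return (fold - 1) % self.k

    def splits(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_idx, test_idx) for folds 0..k-1 in rotation order."""
        idx = np.arange(self.n_samples)
        for fold in range(self.k):
            portion = self.test_portion(fold)
            test = idx[self.assignment == portion]
            train = idx[self.assignment != portion]
            yield train, test


def stratified_folds(labels: Sequence[str] | np.ndarray, k: int, seed: int) -> FoldPlan:
    """Assign samples to k portions, separately within each class.

    Within each class the (seed-shuffled) samples are dealt round-robin, so
    per-class portion sizes differ by at most one and every portion contains
    at least one sample of each class.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for cls in sorted(set(labels)):
        members = np.where(labels == cls)[0]
        if members.size < k:
            raise MalaniError(
                f"class {cls!r} has {members.size} samples, fewer than k={k}; "
                f"choose k <= {members.size}"
            )
        order = rng.permutation(members)
        assignment[order] = np.arange(order.size) % k
    return FoldPlan(k=k, assignment=assignment)


# ---------------------------------------------------------------------------
# PPI network, gene sets, mutations
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """An undirected protein-protein interaction network."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            warnings.warn(f"dropping {len(loops)} self-loop(s) from PPI network")
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node]) if node in self.graph else 0


@dataclass
class GeneSetCollection:
    """Named gene categories plus the size of the reference background."""

    categories: dict[str, set[str]]
    reference_size: int

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ParseError(f"gene set category {name!r} is empty")
        if self.reference_size < 1:
            raise ParseError("reference_size must be positive")

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class MutationTable:
    """Records of (gene, mutation_type), e.g. from genome-wide studies."""

    records: pd.DataFrame  # columns: gene, mutation_type
    vocabulary: tuple[str, ...] = MUTATION_TYPES
    strict: bool = True

    def __post_init__(self) -> None:
        if list(self.records.columns) != ["gene", "mutation_type"]:
            self.records = self.records.rename(
                columns=dict(zip(self.records.columns, ["gene", "mutation_type"]))
            )
        self.records = self.records.drop_duplicates(ignore_index=True)
        if self.strict:
            bad = set(self.records["mutation_type"]) - set(self.vocabulary)
            if bad:
                raise ParseError(f"unknown mutation type(s): {sorted(bad)}")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])

    def types_of(self, gene: str) -> set[str]:
        sel = self.records.loc[self.records["gene"] == gene, "mutation_type"]
        return set(sel)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class InputBundle:
    """Everything a pipeline run may consume."""

    dataset: ExpressionDataset
    ppi: PPINetwork | None = None
    gene_sets: GeneSetCollection | None = None
    mutations: MutationTable | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a TSV expression matrix: first column gene id, header = samples.

    Duplicate gene ids are averaged (probe-to-gene collapsing done upstream
    is the norm; when duplicates slip through we mirror that averaging and
    warn rather than fail).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"expression matrix {path} is empty")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        warnings.warn(
            f"expression matrix contains duplicate gene id(s) {dupes[:5]}; averaging rows"
        )
        df = df.groupby(level=0, sort=False).mean()
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from exc
    return list(df.index), [str(c) for c in df.columns], values


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, label) TSV; labels are case-insensitive."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"labels file {path} needs two tab-separated columns")
    # Tolerate an optional header row.
    if df.iloc[0, 1].strip().lower() not in VALID_LABELS and len(df) > 1:
        df = df.iloc[1:]
    out: dict[str, str] = {}
    for _, (sample, label) in df.iloc[:, :2].iterrows():
        norm = str(label).strip().lower()
        if norm not in VALID_LABELS:
            raise ParseError(
                f"label {label!r} for sample {sample!r} is not one of {VALID_LABELS}"
            )
        out[str(sample).strip()] = norm
    return out


def load_expression_dataset(
    expression_path: str | Path, labels_path: str | Path
) -> ExpressionDataset:
    gene_ids, sample_ids, values = read_expression(expression_path)
    label_map = read_labels(labels_path)
    missing = [s for s in label_map if s not in sample_ids]
    if missing:
        raise ConsistencyError(
            f"sample(s) in labels file missing from expression matrix: {missing[:5]}"
        )
    unlabeled = [s for s in sample_ids if s not in label_map]
    if unlabeled:
        raise ConsistencyError(f"sample(s) lacking a label: {unlabeled[:5]}")
    labels = np.array([label_map[s] for s in sample_ids], dtype=object)
    return ExpressionDataset(gene_ids, sample_ids, values, labels)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI network from SIF (``A pp B``) or a 2-column edge list."""
    g: nx.Graph = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 3:  # SIF: source relation target
                a, _, b = parts
            elif len(parts) == 2:
                a, b = parts
            else:
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop(s) while reading {path}")
    return PPINetwork(graph=g)


def read_gmt(path: str | Path, reference_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes...)."""
    categories: dict[str, set[str]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in categories:
                raise ParseError(f"{path}:{lineno}: duplicate category name {name!r}")
            categories[name] = set(genes)
            universe |= categories[name]
    if reference_size is None:
        reference_size = len(universe)
    return GeneSetCollection(categories=categories, reference_size=reference_size)


def read_mutations(
    path: str | Path,
    vocabulary: tuple[str, ...] = MUTATION_TYPES,
    strict: bool = True,
) -> MutationTable:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"mutation table {path} needs two tab-separated columns")
    if str(df.iloc[0, 0]).strip().lower() == "gene":
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene", "mutation_type"]
    df = df.map(lambda s: str(s).strip())
    return MutationTable(records=df.reset_index(drop=True), vocabulary=vocabulary, strict=strict)


def load_inputs(
    expression_path: str | Path,
    labels_path: str | Path,
    ppi_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    mutations_path: str | Path | None = None,
) -> InputBundle:
    """Load and validate every input file the pipeline may use."""
    bundle = InputBundle(dataset=load_expression_dataset(expression_path, labels_path))
    if ppi_path is not None:
        bundle.ppi = read_ppi(ppi_path)
    if gmt_path is not None:
        bundle.gene_sets = read_gmt(gmt_path)
    if mutations_path is not None:
        bundle.mutations = read_mutations(mutations_path)
    return bundle


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index_label="gene")


def write_labels(ds: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sample}\t{label}\n")


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_mutations(muts: MutationTable, path: str | Path) -> None:
    muts.records.to_csv(path, sep="\t", index=False, header=False)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.categories.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def write_network(graph: nx.Graph, graphml_path: str | Path, edges_path: str | Path) -> None:
    """Write a network as GraphML plus a flat TSV edge list with attributes."""
    nx.write_graphml(graph, graphml_path)
    attrs = sorted({k for _, _, d in graph.edges(data=True) for k in d})
    with open(edges_path, "w") as fh:
        fh.write("\t".join(["source", "target", *attrs]) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            d = graph.edges[a, b]
            row = [a, b] + [str(d.get(k, "")) for k in attrs]
            fh.write("\t".join(row) + "\n")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes
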