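"""Synthetic expression data with planted class-I and class-II structure.

The generator emulates the statistical situation the pipeline is built to
resolve: a labeled (cancer vs normal) intensity matrix in which

* most genes are pure background — i.i.d. log-normal, identically
  distributed in both classes;
* a handful of *fold-change* genes (class I material) have their log-mean
  shifted by ``+/- log(fc)`` in cancer samples;
* a handful of *coordinator pairs* (class II material) carry a class
  signal that is invisible to any per-gene marginal test: each pair
  (a, b) shares a per-sample latent factor z; in cancer both genes load
  ``+z`` while in normal samples gene b loads ``-z``.  Each gene's
  marginal distribution is therefore exactly the same in both classes,
  but the per-sample product a*b switches from positively to negatively
  coupled — the signature the pair-product feature space is designed to
  detect;
* one *linker gene* per coordinator pair, modelling the biology of
  signal linkers that couple a coordinator to the rest of the network:
  the linker loads the pair's latent factor with the same sign flip as
  gene b (at a weaker loading), so its product with gene a is a second,
  weaker class-informative feature.  Linker marginals are likewise
  identical across classes.

All values are exponentiated so the matrix is positive, intensity-like
and compatible with per-sample sum normalization.  Every random draw
flows from a single seed through named substreams, so datasets, PPI
graphs and mutation tables are reproducible independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import (
    MUTATION_TYPES,
    ExpressionDataset,
    MalaniError,
    MutationTable,
    PPINetwork,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_expression",
    "generate_ppi",
    "generate_mutations",
    "simulate_bundle",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults define the desk-scale study conditions used throughout
    the test-suite: 300 genes, 30+30 samples, five coordinator pairs at
    |rho| = 0.9 and ten up- plus ten down-regulated genes at 3-fold
    change.

    ``noise_sd`` is the residual log-scale standard deviation of the
    coordinator and linker genes; together with ``rho`` it fixes the
    latent loading ``lam = noise_sd * sqrt(rho / (1 - rho))`` so that
    the within-class correlation magnitude of a coordinator pair equals
    ``rho`` exactly.  ``latent`` selects the latent-factor law:
    ``"two_state"`` (a +/-1 pathway on/off switch, the default) or
    ``"gaussian"``.  ``linker_loading`` is the (absolute, log-scale)
    loading of each pair's linker gene on the pair latent; 0 disables
    linkers.
    """

    G: int = 300
    n_cancer: int = 30
    n_normal: int = 30
    n_up: int = 10
    n_down: int = 10
    fc: float = 3.0
    n_pairs: int = 5
    rho: float = 0.9
    noise_sd: float = 0.3
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    latent: str = "two_state"
    linker_loading: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise MalaniError("rho must lie strictly between 0 and 1")
        for name in ("G", "n_cancer", "n_normal", "n_up", "n_down", "n_pairs"):
            if getattr(self, name) < 0:
                raise MalaniError(f"{name} must be >= 0")
        if self.n_planted > self.G:
            raise MalaniError(
                "planted genes (coordinators + linkers + fold-change) exceed G"
            )
        if self.latent not in ("two_state", "gaussian"):
            raise MalaniError("latent must be 'two_state' or 'gaussian'")
        if self.fc <= 0 or self.noise_sd <= 0 or self.base_log_sd <= 0:
            raise MalaniError("fc, noise_sd and base_log_sd must be positive")
        if self.linker_loading < 0:
            raise MalaniError("linker_loading must be >= 0")

    @property
    def n_linkers(self) -> int:
        return self.n_pairs if self.linker_loading > 0 else 0

    @property
    def n_planted(self) -> int:
        return 2 * self.n_pairs + self.n_linkers + self.n_up + self.n_down

    @property
    def loading(self) -> float:
        """Latent loading giving within-class |correlation| == rho."""
        return self.noise_sd * np.sqrt(self.rho / (1.0 - self.rho))


@dataclass
class GroundTruth:
    """Machine-readable record of what was planted where."""

    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    coordinator_pairs: list[tuple[str, str]] = field(default_factory=list)
    linker_genes: list[str] = field(default_factory=list)
    mediator_nodes: list[str] = field(default_factory=list)

    @property
    def coordinator_genes(self) -> set[str]:
        return {g for pair in self.coordinator_pairs for g in pair}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up_genes": self.up_genes,
            "down_genes": self.down_genes,
            "coordinator_pairs": [list(p) for p in self.coordinator_pairs],
            "linker_genes": self.linker_genes,
            "mediator_nodes": self.mediator_nodes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            up_genes=list(payload["up_genes"]),
            down_genes=list(payload["down_genes"]),
            coordinator_pairs=[tuple(p) for p in payload["coordinator_pairs"]],
            linker_genes=list(payload.get("linker_genes", [])),
            mediator_nodes=list(payload.get("mediator_nodes", [])),
        )


def gene_names(G: int) -> list[str]:
    width = max(4, len(str(G)))
    return [f"G{i:0{width}d}" for i in range(1, G + 1)]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # Named substream: independent generators per artifact, one root seed.
    return np.random.default_rng([cfg.seed, stream])


def generate_expression(cfg: SimConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a labeled expression matrix and its ground truth."""
    rng = _rng(cfg, 0)
    G, S = cfg.G, cfg.n_cancer + cfg.n_normal
    genes = gene_names(G)
    samples = [f"C{i:03d}" for i in range(1, cfg.n_cancer + 1)] + [
        f"N{i:03d}" for i in range(1, cfg.n_normal + 1)
    ]
    labels = np.array(
        ["cancer"] * cfg.n_cancer + ["normal"] * cfg.n_normal, dtype=object
    )
    is_cancer = labels == "cancer"

    # Background: i.i.d. log-normal, identical in both classes.
    log_x = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=(G, S))

    # Planted roles occupy random, disjoint gene slots.
    slots = rng.choice(G, size=cfg.n_planted, replace=False)
    pair_slots = slots[: 2 * cfg.n_pairs].reshape(cfg.n_pairs, 2)
    off = 2 * cfg.n_pairs
    linker_slots = slots[off : off + cfg.n_linkers]
    off += cfg.n_linkers
    up_slots = slots[off : off + cfg.n_up]
    down_slots = slots[off + cfg.n_up :]

    log_fc = np.log(cfg.fc)
    log_x[np.ix_(up_slots, np.where(is_cancer)[0])] += log_fc
    log_x[np.ix_(down_slots, np.where(is_cancer)[0])] -= log_fc

    lam = cfg.loading
    sign_flip = np.where(is_cancer, 1.0, -1.0)  # sign of the flipped loading
    for p, (a_slot, b_slot) in enumerate(pair_slots):
        if cfg.latent == "two_state":
            # Balanced on/off states within each class: every class holds
            # (up to rounding) equally many +1 and -1 samples, so class
            # means depend on the latent only through residual noise and
            # the pair signal stays confined to per-sample products.
            z = np.empty(S)
            for cls_mask in (is_cancer, ~is_cancer):
                n_cls = int(cls_mask.sum())
                states = np.resize([1.0, -1.0], n_cls)
                z[cls_mask] = rng.permutation(states)
        else:
            z = rng.normal(0.0, 1.0, size=S)
        eps_a = rng.normal(0.0, cfg.noise_sd, size=S)
        eps_b = rng.normal(0.0, cfg.noise_sd, size=S)
        # Gene a loads +z in both classes; gene b flips sign in normals,
        # so each marginal is class-invariant while cov(a, b) switches sign.
        log_x[a_slot] = cfg.base_log_mean + lam * z + eps_a
        log_x[b_slot] = cfg.base_log_mean + sign_flip * lam * z + eps_b
        if cfg.n_linkers:
            eps_m = rng.normal(0.0, cfg.noise_sd, size=S)
            log_x[linker_slots[p]] = (
                cfg.base_log_mean + sign_flip * cfg.linker_loading * z + eps_m
            )

    ds = ExpressionDataset(
        gene_ids=genes, sample_ids=samples, values=np.exp(log_x), labels=labels
    )
    truth = GroundTruth(
        up_genes=[genes[i] for i in np.sort(up_slots)],
        down_genes=[genes[i] for i in np.sort(down_slots)],
        coordinator_pairs=[
            tuple(sorted((genes[a], genes[b]))) for a, b in pair_slots
        ],
        linker_genes=[genes[i] for i in linker_slots],
    )
    return ds, truth


def generate_ppi(
    cfg: SimConfig,
    attach_m: int = 2,
    truth: GroundTruth | None = None,
    n_mediators: int = 5,
) -> PPINetwork:
    """A connected preferential-attachment (scale-free) graph over all genes.

    The highest-degree nodes act as natural path mediators; when a
    ``truth`` record is supplied they are written to its
    ``mediator_nodes`` field.
    """
    if attach_m < 1:
        raise MalaniError("attach_m must be >= 1")
    if cfg.G < attach_m + 1:
        raise MalaniError("G must exceed attach_m")
    seed = int(_rng(cfg, 1).integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(cfg.G, attach_m, seed=seed)
    mapping = dict(enumerate(gene_names(cfg.G)))
    g = nx.relabel_nodes(g, mapping)
    if truth is not None:
        by_degree = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))
        truth.mediator_nodes = [n for n, _ in by_degree[:n_mediators]]
    return PPINetwork(graph=g)


def generate_mutations(
    cfg: SimConfig,
    genes: Sequence[str],
    rate: float,
    exclude: Iterable[str] = (),
    vocabulary: tuple[str, ...] = MUTATION_TYPES,
) -> MutationTable:
    """Assign 1-4 mutation types to a ``rate`` fraction of genes.

    Genes in ``exclude`` (the planted coordinator genes, so the class-II
    ground truth stays clean) never receive a mutation.
    """
    if not (0.0 <= rate <= 1.0):
        raise MalaniError("rate must lie in [0, 1]")
    rng = _rng(cfg, 2)
    excluded = set(exclude)
    rows: list[tuple[str, str]] = []
    for gene in genes:
        if gene in excluded or rng.random() >= rate:
            continue
        n_types = int(rng.integers(1, 5))
        for mtype in rng.choice(vocabulary, size=n_types, replace=False):
            rows.append((gene, str(mtype)))
    df = pd.DataFrame(rows, columns=["gene", "mutation_type"])
    return MutationTable(records=df, vocabulary=vocabulary)


def simulate_bundle(
    cfg: SimConfig,
    attach_m: int = 2,
    mutation_rate: float = 0.15,
) -> tuple[ExpressionDataset, GroundTruth, PPINetwork, MutationTable]:
    """Generate the full synthetic study: matrix, truth, PPI and mutations."""
    ds, truth = generate_expression(cfg)
    ppi = generate_ppi(cfg, attach_m=attach_m, truth=truth)
    muts = generate_mutations(
        cfg,
        ds.gene_ids,
        mutation_rate,
        exclude=truth.coordinator_genes | set(truth.linker_genes),
    )
    return ds, truth, ppi, muts
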