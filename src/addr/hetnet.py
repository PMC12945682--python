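"""Heterogeneous biomedical knowledge graphs ("hetnets").

A hetnet is a graph with typed nodes (drug, disease, gene, ...) and typed
edges (indication, target, association, ...).  The metagraph *schema* is the
set of ``(source_type, edge_type, target_type)`` triples that occur.  Edges
are stored with a direction, but degree counting and path traversal treat
them as traversable both ways.

This module provides the in-memory container, TSV I/O, and a synthetic
generator that plants known drug->disease indications (with supporting
drug-gene-disease connectivity) as recoverable ground truth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SchemaTriple = tuple[str, str, str]
EdgeTuple = tuple[str, str, str]  # (source_id, edge_type, target_id)


class HetnetError(ValueError):
    """Raised for malformed graphs or graph files."""


@dataclass
class Hetnet:
    """Typed-node / typed-edge graph with an inferred metagraph schema.

    Parameters
    ----------
    nodes
        Mapping from node id to node type.  Node ids are opaque strings and
        must be unique (dict keys enforce this).
    edges
        List of ``(source_id, edge_type, target_id)`` tuples.  Parallel
        edges are allowed (the edge list is a multiset).
    names
        Optional display names per node id.
    """

    nodes: dict[str, str]
    edges: list[EdgeTuple]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._adjacency_cache: dict[str, dict[str, list[str]]] | None = None

    # ------------------------------------------------------------------ #
    # invariants

    def validate(self) -> None:
        for i, (s, e, t) in enumerate(self.edges):
            if s not in self.nodes:
                raise HetnetError(f"edge row {i}: unknown source node {s!r}")
            if t not in self.nodes:
                raise HetnetError(f"edge row {i}: unknown target node {t!r}")
            if not e:
                raise HetnetError(f"edge row {i}: empty edge type")

    @property
    def schema(self) -> frozenset[SchemaTriple]:
        """Metagraph: the set of observed (source_type, edge_type, target_type)."""
        return frozenset(
            (self.nodes[s], e, self.nodes[t]) for s, e, t in self.edges
        )

    # ------------------------------------------------------------------ #
    # queries

    def node_ids_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t == node_type)

    @property
    def node_types(self) -> set[str]:
        return set(self.nodes.values())

    def _adjacency(self) -> dict[str, dict[str, list[str]]]:
        """edge_type -> node -> neighbor list (both directions, with multiplicity)."""
        if self._adjacency_cache is None:
            adj: dict[str, dict[str, list[str]]] = defaultdict(
                lambda: defaultdict(list)
            )
            for s, e, t in self.edges:
                adj[e][s].append(t)
                adj[e][t].append(s)
            self._adjacency_cache = {
                e: dict(nbrs) for e, nbrs in adj.items()
            }
        return self._adjacency_cache

    def neighbors(self, node_id: str, edge_type: str) -> list[str]:
        """Neighbors of ``node_id`` via edges of ``edge_type`` (either direction)."""
        return self._adjacency().get(edge_type, {}).get(node_id, [])

    def degree(self, node_id: str, edge_type: Optional[str] = None) -> int:
        """Number of incident edges, optionally restricted to one edge type.

        Direction-agnostic; parallel edges each count once, and a self-loop
        counts twice (once per endpoint).
        """
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        adj = self._adjacency()
        if edge_type is not None:
            return len(adj.get(edge_type, {}).get(node_id, ()))
        return sum(len(nbrs.get(node_id, ())) for nbrs in adj.values())

    def edge_pairs(self, edge_type: str) -> set[tuple[str, str]]:
        """Distinct (source, target) pairs carrying ``edge_type``."""
        return {(s, t) for s, e, t in self.edges if e == edge_type}

    # ------------------------------------------------------------------ #
    # I/O

    def write(self, nodes_path, edges_path) -> None:
        nodes_df = pd.DataFrame(
            {
                "id": sorted(self.nodes),
                "type": [self.nodes[n] for n in sorted(self.nodes)],
            }
        )
        nodes_df["name"] = [self.names.get(n, n) for n in nodes_df["id"]]
        nodes_df.to_csv(nodes_path, sep="\t", index=False)
        edges_df = pd.DataFrame(
            sorted(self.edges), columns=["source", "edge_type", "target"]
        )
        edges_df.to_csv(edges_path, sep="\t", index=False)


def load_hetnet(nodes_path, edges_path) -> Hetnet:
    """Read a hetnet from two TSV files.

    ``nodes_path`` needs columns ``id`` and ``type`` (``name`` optional);
    ``edges_path`` needs ``source``, ``edge_type``, ``target``.  The schema
    is inferred from the observed edge triples.
    """
    nodes_df = pd.read_csv(nodes_path, sep="\t", dtype=str)
    for col in ("id", "type"):
        if col not in nodes_df.columns:
            raise HetnetError(f"nodes file missing column {col!r}")
    dupes = nodes_df["id"][nodes_df["id"].duplicated()]
    if len(dupes):
        raise HetnetError(f"duplicate node id {dupes.iloc[0]!r} in nodes file")
    nodes = dict(zip(nodes_df["id"], nodes_df["type"]))
    names = (
        dict(zip(nodes_df["id"], nodes_df["name"]))
        if "name" in nodes_df.columns
        else {}
    )
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str)
    if len(edges_df.columns) and set(edges_df.columns) >= {
        "source",
        "edge_type",
        "target",
    }:
        edges = list(
            edges_df[["source", "edge_type", "target"]].itertuples(
                index=False, name=None
            )
        )
    elif len(edges_df) == 0:
        edges = []
    else:
        raise HetnetError("edges file missing source/edge_type/target columns")
    return Hetnet(nodes=nodes, edges=edges, names=names)


# ---------------------------------------------------------------------- #
# synthetic generator


@dataclass
class SynthKGConfig:
    """Configuration for the synthetic knowledge-graph generator.

    The generator emulates, at reduced scale, a harmonized biomedical
    knowledge graph with drug/disease/gene/pathway nodes and
    indication/contraindication/off-label/target/association relations.
    ``n_planted_indications`` drug->disease indication edges are planted as
    ground truth; each planted pair is additionally connected through
    ``n_support_genes`` drug-gene-disease paths so the signal is learnable
    from multi-hop topology even when the direct edge is held out.
    """

    node_counts: Mapping[str, int]
    edge_densities: Mapping[SchemaTriple, float]
    n_planted_indications: int = 0
    n_support_genes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for t, n in self.node_counts.items():
            if n < 0:
                raise HetnetError(f"negative count for node type {t!r}")
        for triple, p in self.edge_densities.items():
            if not 0.0 <= p <= 1.0:
                raise HetnetError(f"density for {triple} not in [0,1]: {p}")
        n_drug = self.node_counts.get("drug", 0)
        n_disease = self.node_counts.get("disease", 0)
        if self.n_planted_indications > n_drug * n_disease:
            raise HetnetError(
                "n_planted_indications exceeds |drugs| x |diseases|"
            )
        if self.n_planted_indications > 0 and self.node_counts.get("gene", 0) == 0:
            if self.n_support_genes > 0:
                raise HetnetError("support genes requested but no gene nodes")


def default_kg_config(seed: int = 0, **overrides) -> SynthKGConfig:
    """A small benchmark-scale configuration (50 drugs, 20 diseases, 100 genes)."""
    params = dict(
        node_counts={"drug": 50, "disease": 20, "gene": 100, "pathway": 10},
        edge_densities={
            ("drug", "indication", "disease"): 0.01,
            ("drug", "contraindication", "disease"): 0.01,
            ("drug", "off_label", "disease"): 0.005,
            ("drug", "target", "gene"): 0.02,
            ("gene", "association", "disease"): 0.02,
            ("gene", "member", "pathway"): 0.05,
        },
        n_planted_indications=40,
        n_support_genes=2,
        seed=seed,
    )
    params.update(overrides)
    return SynthKGConfig(**params)


def generate_synthetic_kg(
    config: SynthKGConfig,
) -> tuple[Hetnet, list[tuple[str, str]]]:
    """Generate a random hetnet plus its planted-indication ground truth.

    Returns ``(hetnet, ground_truth)`` where ``ground_truth`` is the sorted
    list of planted (drug_id, disease_id) pairs.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nodes: dict[str, str] = {}
    ids_by_type: dict[str, list[str]] = {}
    for node_type in sorted(config.node_counts):
        n = config.node_counts[node_type]
        width = max(4, len(str(n)))
        ids = [f"{node_type}_{i:0{width}d}" for i in range(n)]
        ids_by_type[node_type] = ids
        for i in ids:
            nodes[i] = node_type

    # planted indications: distinct (drug, disease) pairs
    drugs = ids_by_type.get("drug", [])
    diseases = ids_by_type.get("disease", [])
    planted: list[tuple[str, str]] = []
    if config.n_planted_indications:
        n_pairs = len(drugs) * len(diseases)
        chosen = rng.choice(
            n_pairs, size=config.n_planted_indications, replace=False
        )
        planted = sorted(
            (drugs[k // len(diseases)], diseases[k % len(diseases)])
            for k in chosen
        )
    planted_set = set(planted)

    edges: list[EdgeTuple] = []
    for triple in sorted(config.edge_densities):
        src_type, edge_type, tgt_type = triple
        p = config.edge_densities[triple]
        src_ids = ids_by_type.get(src_type, [])
        tgt_ids = ids_by_type.get(tgt_type, [])
        if not src_ids or not tgt_ids or p == 0.0:
            continue
        mask = rng.random((len(src_ids), len(tgt_ids))) < p
        for i, j in zip(*np.nonzero(mask)):
            s, t = src_ids[i], tgt_ids[j]
            if edge_type == "indication" and (s, t) in planted_set:
                continue  # planted edges added below exactly once
            edges.append((s, edge_type, t))

    gene_ids = ids_by_type.get("gene", [])
    support_edges: set[EdgeTuple] = set()
    for drug, disease in planted:
        edges.append((drug, "indication", disease))
        if config.n_support_genes and gene_ids:
            genes = rng.choice(
                len(gene_ids),
                size=min(config.n_support_genes, len(gene_ids)),
                replace=False,
            )
            for g in genes:
                support_edges.add((drug, "target", gene_ids[g]))
                support_edges.add((gene_ids[g], "association", disease))
    # avoid duplicating support edges that random sampling already produced
    edges.extend(sorted(support_edges.difference(edges)))

    return Hetnet(nodes=nodes, edges=sorted(edges)), planted


def write_ground_truth(pairs: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(sorted(pairs), columns=["drug_id", "disease_id"]).to_csv(
        path, sep="\t", index=False
    )


def load_ground_truth(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df[["drug_id", "disease_id"]].itertuples(index=False, name=None))
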