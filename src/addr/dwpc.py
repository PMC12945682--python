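"""Metapath enumeration and degree-weighted path counts (DWPC).

A metapath is a schema of alternating node and edge types, e.g.
``drug -target- gene -association- disease``.  For a metapath lambda and a
node pair (s, t), the DWPC sums, over all path instances of that type, the
product of each intermediate node's degree raised to ``-w`` (the damping
exponent, default 0.4).  Many connecting paths raise the feature value;
paths through high-degree hub nodes are down-weighted.

Two path semantics are supported:

``paths`` (default)
    node-distinct paths only — no node may repeat, which prevents
    degenerate backtracking walks from inflating the count;
``walks``
    node repeats allowed; computed by a sparse-matrix product chain.

Two degree conventions are supported for the damping term at an
intermediate node traversed in via edge type ``e_in`` and out via ``e_out``:

``per-edge-type`` (default)
    incident edges whose type is ``e_in`` or ``e_out``;
``total``
    all incident edges regardless of type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .hetnet import Hetnet, HetnetError, SchemaTriple

DEFAULT_DAMPING = 0.4
DEFAULT_MAX_LENGTH = 4


@dataclass(frozen=True)
class Metapath:
    """Alternating node-type / edge-type sequence with fixed endpoints."""

    node_types: tuple[str, ...]
    edge_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.node_types) != len(self.edge_types) + 1:
            raise ValueError("node_types must be one longer than edge_types")
        if not self.edge_types:
            raise ValueError("metapath needs at least one edge")

    @property
    def length(self) -> int:
        return len(self.edge_types)

    @property
    def source_type(self) -> str:
        return self.node_types[0]

    @property
    def target_type(self) -> str:
        return self.node_types[-1]

    def abbrev(self) -> str:
        parts = [self.node_types[0]]
        for e, n in zip(self.edge_types, self.node_types[1:]):
            parts.extend([e, n])
        return ":".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.abbrev()


def enumerate_metapaths(
    schema: Iterable[SchemaTriple],
    source_type: str,
    target_type: str,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> list[Metapath]:
    """All schema-valid metapaths from ``source_type`` to ``target_type``.

    Schema triples are traversable in both directions, but a step may not
    immediately reverse the triple just traversed: bounce-back schemas like
    drug-indication-disease-indication-drug add no new connectivity beyond
    the direct relation and would otherwise multiply without bound.
    Results are deduplicated and ordered by (length, abbreviation).
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    schema = list(schema)
    known_types = {t for s, _, u in schema for t in (s, u)}
    for nt in (source_type, target_type):
        if nt not in known_types:
            raise HetnetError(f"node type {nt!r} absent from schema")

    # metagraph adjacency: type -> sorted [(edge_type, next_type, triple, fwd)]
    steps: dict[str, list[tuple[str, str, SchemaTriple, bool]]] = {}
    for s, e, t in schema:
        steps.setdefault(s, []).append((e, t, (s, e, t), True))
        if s != t:
            steps.setdefault(t, []).append((e, s, (s, e, t), False))
    for k in steps:
        steps[k] = sorted(set(steps[k]))

    found: set[Metapath] = set()

    def extend(
        node_seq: tuple[str, ...],
        edge_seq: tuple[str, ...],
        prev: Optional[tuple[SchemaTriple, bool]],
    ) -> None:
        here = node_seq[-1]
        if here == target_type and edge_seq:
            found.add(Metapath(node_seq, edge_seq))
        if len(edge_seq) == max_length:
            return
        for e, nxt, triple, fwd in steps.get(here, ()):
            if (
                prev is not None
                and triple == prev[0]
                and fwd != prev[1]
                and triple[0] != triple[2]
            ):
                continue  # immediate reversal of the same schema triple
            extend(node_seq + (nxt,), edge_seq + (e,), (triple, fwd))

    extend((source_type,), (), None)
    return sorted(found, key=lambda m: (m.length, m.abbrev()))


# ---------------------------------------------------------------------- #
# degree damping helpers


def _step_degree(
    hetnet: Hetnet, node: str, e_in: str, e_out: str, degree_mode: str
) -> int:
    if degree_mode == "total":
        return hetnet.degree(node)
    if degree_mode == "per-edge-type":
        d = hetnet.degree(node, e_in)
        if e_out != e_in:
            d += hetnet.degree(node, e_out)
        return d
    raise ValueError(f"unknown degree_mode {degree_mode!r}")


def _check_endpoints(
    hetnet: Hetnet, metapath: Metapath, source_id: str, target_id: str
) -> None:
    for node, want in ((source_id, metapath.source_type), (target_id, metapath.target_type)):
        if node not in hetnet.nodes:
            raise KeyError(f"unknown node {node!r}")
        if hetnet.nodes[node] != want:
            raise HetnetError(
                f"node {node!r} has type {hetnet.nodes[node]!r}, metapath "
                f"endpoint requires {want!r}"
            )


# ---------------------------------------------------------------------- #
# DFS route (node-distinct paths; also supports walks for cross-checks)


def _dwpc_from_source(
    hetnet: Hetnet,
    metapath: Metapath,
    source_id: str,
    damping: float,
    path_semantics: str,
    degree_mode: str,
) -> dict[str, float]:
    """DWPC from one source to every reachable target, via pruned DFS."""
    node_distinct = path_semantics == "paths"
    if path_semantics not in ("paths", "walks"):
        raise ValueError(f"unknown path_semantics {path_semantics!r}")
    L = metapath.length
    out: dict[str, float] = {}
    visited = {source_id}

    def rec(node: str, depth: int, weight: float) -> None:
        if depth == L:
            out[node] = out.get(node, 0.0) + weight
            return
        e = metapath.edge_types[depth]
        next_type = metapath.node_types[depth + 1]
        for nb in hetnet.neighbors(node, e):
            if hetnet.nodes[nb] != next_type:
                continue
            if node_distinct and nb in visited:
                continue
            w = weight
            if depth + 1 < L:  # nb is an intermediate node: damp it
                deg = _step_degree(
                    hetnet, nb, e, metapath.edge_types[depth + 1], degree_mode
                )
                w *= float(deg) ** (-damping) if deg else 0.0
            if node_distinct:
                visited.add(nb)
            rec(nb, depth + 1, w)
            if node_distinct:
                visited.discard(nb)

    rec(source_id, 0, 1.0)
    return out


def dwpc(
    hetnet: Hetnet,
    metapath: Metapath,
    source_id: str,
    target_id: str,
    damping: float = DEFAULT_DAMPING,
    *,
    path_semantics: str = "paths",
    degree_mode: str = "per-edge-type",
) -> float:
    """DWPC between one (source, target) pair.

    The product over an empty intermediate set is 1, so a bare length-1
    metapath contributes 1.0 per connecting edge.  Returns 0.0 when no path
    of the metapath's type exists.
    """
    _check_endpoints(hetnet, metapath, source_id, target_id)
    reached = _dwpc_from_source(
        hetnet, metapath, source_id, damping, path_semantics, degree_mode
    )
    return reached.get(target_id, 0.0)


# ---------------------------------------------------------------------- #
# all-pairs route


def _typed_adjacency_matrix(
    hetnet: Hetnet,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    row_type: str,
    col_type: str,
    edge_type: str,
) -> sparse.csr_matrix:
    ri = {n: i for i, n in enumerate(row_ids)}
    ci = {n: i for i, n in enumerate(col_ids)}
    rows, cols = [], []
    for s, e, t in hetnet.edges:
        if e != edge_type:
            continue
        if hetnet.nodes[s] == row_type and hetnet.nodes[t] == col_type:
            rows.append(ri[s])
            cols.append(ci[t])
        # undirected traversal: reversed orientation also crosses row->col
        # (a self-loop is deliberately counted from both ends, matching the
        # adjacency-list traversal)
        if hetnet.nodes[t] == row_type and hetnet.nodes[s] == col_type:
            rows.append(ri[t])
            cols.append(ci[s])
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(col_ids))
    )


def _dwwc_matrix(
    hetnet: Hetnet,
    metapath: Metapath,
    damping: float,
    degree_mode: str,
) -> tuple[list[str], list[str], np.ndarray]:
    """Degree-weighted *walk* count for all pairs via sparse products."""
    level_ids = [hetnet.node_ids_of_type(t) for t in metapath.node_types]
    mat = _typed_adjacency_matrix(
        hetnet,
        level_ids[0],
        level_ids[1],
        metapath.node_types[0],
        metapath.node_types[1],
        metapath.edge_types[0],
    )
    for i in range(1, metapath.length):
        ids = level_ids[i]
        damp = np.zeros(len(ids))
        for j, node in enumerate(ids):
            deg = _step_degree(
                hetnet,
                node,
                metapath.edge_types[i - 1],
                metapath.edge_types[i],
                degree_mode,
            )
            damp[j] = float(deg) ** (-damping) if deg else 0.0
        nxt = _typed_adjacency_matrix(
            hetnet,
            ids,
            level_ids[i + 1],
            metapath.node_types[i],
            metapath.node_types[i + 1],
            metapath.edge_types[i],
        )
        mat = sparse.csr_matrix(mat.multiply(damp[np.newaxis, :])) @ nxt
    dense = np.asarray(mat.todense(), dtype=float)
    return level_ids[0], level_ids[-1], dense


def dwpc_all_pairs(
    hetnet: Hetnet,
    metapath: Metapath,
    damping: float = DEFAULT_DAMPING,
    *,
    path_semantics: str = "paths",
    degree_mode: str = "per-edge-type",
    sources: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """DWPC matrix over all (source, target) node pairs of the endpoint types.

    Walk semantics use a damped sparse-matrix product chain; node-distinct
    path semantics use a pruned depth-first traversal per source node.
    Entry (s, t) equals ``dwpc(hetnet, metapath, s, t, ...)``.
    """
    if sources is None:
        sources = hetnet.node_ids_of_type(metapath.source_type)
    targets = hetnet.node_ids_of_type(metapath.target_type)
    if path_semantics == "walks" and sources == hetnet.node_ids_of_type(
        metapath.source_type
    ):
        rows, cols, dense = _dwwc_matrix(hetnet, metapath, damping, degree_mode)
        return pd.DataFrame(dense, index=rows, columns=cols)
    values = np.zeros((len(sources), len(targets)))
    tidx = {t: j for j, t in enumerate(targets)}
    for i, s in enumerate(sources):
        reached = _dwpc_from_source(
            hetnet, metapath, s, damping, path_semantics, degree_mode
        )
        for t, v in reached.items():
            values[i, tidx[t]] = v
    return pd.DataFrame(values, index=list(sources), columns=targets)


# ---------------------------------------------------------------------- #
# prior feature


def prior_feature(
    hetnet: Hetnet,
    drug_id: str,
    disease_id: str,
    edge_type: str = "indication",
) -> float:
    """Degree-based prior probability of indication for a (drug, disease) pair.

    Defined as ``deg_ind(drug) * deg_ind(disease) / n_ind**2`` clipped to
    [0, 1], where degrees and the total count ``n_ind`` refer to indication
    edges only.  Pairs involving well-indicated drugs and prevalent diseases
    receive a larger prior; the value is 0 when the graph has no indication
    edges.
    """
    for node in (drug_id, disease_id):
        if node not in hetnet.nodes:
            raise KeyError(f"unknown node {node!r}")
    n_edges = sum(1 for _, e, _ in hetnet.edges if e == edge_type)
    if n_edges == 0:
        return 0.0
    value = (
        hetnet.degree(drug_id, edge_type)
        * hetnet.degree(disease_id, edge_type)
        / n_edges**2
    )
    return float(min(1.0, max(0.0, value)))


# ---------------------------------------------------------------------- #
# feature table


def build_feature_table(
    hetnet: Hetnet,
    metapaths: Optional[Sequence[Metapath]] = None,
    damping: float = DEFAULT_DAMPING,
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    source_type: str = "drug",
    target_type: str = "disease",
    label_edge_type: str = "indication",
    include_prior: bool = True,
    path_semantics: str = "paths",
    degree_mode: str = "per-edge-type",
) -> pd.DataFrame:
    """Per-(drug, disease) DWPC feature table plus the degree-based prior.

    When ``metapaths`` is None all schema-valid metapaths up to
    ``max_length`` are used, except the bare single-edge metapath of the
    label edge type: under node-distinct path semantics that feature is an
    indicator of the very edge being predicted and would leak the label.
    Columns are deterministically ordered (metapath abbreviations, then
    ``prior``); the index is a (drug_id, disease_id) MultiIndex.
    """
    if metapaths is None:
        metapaths = [
            m
            for m in enumerate_metapaths(
                hetnet.schema, source_type, target_type, max_length
            )
            if not (m.length == 1 and m.edge_types[0] == label_edge_type)
        ]
    drugs = hetnet.node_ids_of_type(source_type)
    diseases = hetnet.node_ids_of_type(target_type)
    index = pd.MultiIndex.from_product(
        [drugs, diseases], names=["drug_id", "disease_id"]
    )
    table = pd.DataFrame(index=index)
    for m in metapaths:
        mat = dwpc_all_pairs(
            hetnet,
            m,
            damping,
            path_semantics=path_semantics,
            degree_mode=degree_mode,
        )
        table[m.abbrev()] = mat.loc[drugs, diseases].to_numpy().ravel()
    if include_prior:
        n_edges = sum(1 for _, e, _ in hetnet.edges if e == label_edge_type)
        if n_edges:
            d_drug = np.array([hetnet.degree(d, label_edge_type) for d in drugs])
            d_dis = np.array([hetnet.degree(d, label_edge_type) for d in diseases])
            prior = np.clip(np.outer(d_drug, d_dis) / n_edges**2, 0.0, 1.0)
        else:
            prior = np.zeros((len(drugs), len(diseases)))
        table["prior"] = prior.ravel()
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise HetnetError("non-finite feature values")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)
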