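"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities straight from the raw edge list /
raw tables, independently of the package's adjacency and matrix machinery,
so implementation and check never share a code path.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from addr.hetnet import Hetnet


def make_random_hetnet(
    rng: np.random.Generator,
    n_nodes: int = 20,
    n_edges: int | None = None,
    node_types: tuple[str, ...] = ("drug", "disease", "gene", "anatomy"),
    edge_types: tuple[str, ...] = ("e1", "e2", "e3"),
) -> Hetnet:
    """Random typed multigraph used across oracle-equivalence tests."""
    k = int(rng.integers(2, len(node_types) + 1))
    use_types = node_types[:k]
    nodes = {
        f"n{i:03d}": use_types[int(rng.integers(k))] for i in range(n_nodes)
    }
    ids = list(nodes)
    if n_edges is None:
        n_edges = int(rng.integers(n_nodes, 2 * n_nodes))
    edges = []
    for _ in range(n_edges):
        s = ids[int(rng.integers(n_nodes))]
        t = ids[int(rng.integers(n_nodes))]
        e = edge_types[int(rng.integers(len(edge_types)))]
        edges.append((s, e, t))
    return Hetnet(nodes=nodes, edges=edges)


def oracle_degree(net: Hetnet, node: str, edge_type: str | None = None) -> int:
    """Degree by brute-force scan of the raw edge list."""
    count = 0
    for s, e, t in net.edges:
        if edge_type is not None and e != edge_type:
            continue
        if s == node:
            count += 1
        if t == node:
            count += 1
    return count


def oracle_dwpc(
    net: Hetnet,
    metapath,
    source: str,
    target: str,
    damping: float = 0.4,
    node_distinct: bool = True,
) -> float:
    """Exhaustive path/walk enumeration straight off the edge multiset.

    Parallel edges multiply the instance count; an intermediate node's
    damping degree counts its incident edges of the step's in/out types.
    """
    mult = Counter()
    for s, e, t in net.edges:
        mult[(s, e, t)] += 1

    def step_degree(v: str, types: set[str]) -> int:
        d = 0
        for (a, e, b), c in mult.items():
            if e not in types:
                continue
            if a == v:
                d += c
            if b == v:
                d += c
        return d

    total = 0.0
    L = metapath.length

    def rec(path: list[str], weight: float) -> None:
        nonlocal total
        depth = len(path) - 1
        node = path[-1]
        if depth == L:
            if node == target:
                total += weight
            return
        e = metapath.edge_types[depth]
        next_type = metapath.node_types[depth + 1]
        for (a, ee, b), c in mult.items():
            if ee != e:
                continue
            nbrs = []
            if a == node:
                nbrs.append(b)
            if b == node:
                nbrs.append(a)
            for nb in nbrs:
                if net.nodes[nb] != next_type:
                    continue
                if node_distinct and nb in path:
                    continue
                w = weight * c
                if depth + 1 < L:
                    deg = step_degree(nb, {e, metapath.edge_types[depth + 1]})
                    w *= deg ** (-damping) if deg else 0.0
                rec(path + [nb], w)

    rec([source], 1.0)
    return total


def oracle_metapaths(schema, source_type, target_type, max_length):
    """Breadth-first expansion over the metagraph, independent of the
    package's enumerator.  A hop may not immediately undo the previous hop
    along the same schema triple (the no-bounce-back contract)."""
    frontier = [((source_type,), (), None)]
    results = set()
    for _ in range(max_length):
        nxt = []
        for node_seq, edge_seq, last_hop in frontier:
            here = node_seq[-1]
            for s, e, t in schema:
                hops = []
                if s == here:
                    hops.append((e, t, ((s, e, t), "fwd")))
                if t == here:
                    hops.append((e, s, ((s, e, t), "rev")))
                for e_, t_, hop in hops:
                    if (
                        last_hop is not None
                        and hop[0] == last_hop[0]
                        and hop[1] != last_hop[1]
                        and hop[0][0] != hop[0][2]
                    ):
                        continue
                    cand = (node_seq + (t_,), edge_seq + (e_,), hop)
                    nxt.append(cand)
                    if t_ == target_type:
                        results.add(cand[:2])
        frontier = nxt
    return results


@pytest.fixture
def tiny_dgz() -> Hetnet:
    """One drug-gene-disease chain; the gene has total degree 2."""
    return Hetnet(
        nodes={"d1": "drug", "g1": "gene", "z1": "disease"},
        edges=[("d1", "target", "g1"), ("g1", "association", "z1")],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
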