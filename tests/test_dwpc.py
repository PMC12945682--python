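import math

import numpy as np
import pandas as pd
import pytest

from addr.hetnet import Hetnet, HetnetError
from addr.dwpc import (
    Metapath,
    build_feature_table,
    dwpc,
    dwpc_all_pairs,
    enumerate_metapaths,
    prior_feature,
)

from conftest import make_random_hetnet, oracle_dwpc, oracle_metapaths

DGZ = Metapath(("drug", "gene", "disease"), ("target", "association"))


class TestEnumerateMetapaths:
    def test_single_edge_schema(self):
        schema = {("drug", "indication", "disease")}
        mps = enumerate_metapaths(schema, "drug", "disease", 4)
        assert len(mps) == 1
        assert mps[0].edge_types == ("indication",)

    def test_two_hop_path_included(self):
        schema = {
            ("drug", "target", "gene"),
            ("gene", "association", "disease"),
        }
        mps = enumerate_metapaths(schema, "drug", "disease", 2)
        assert DGZ in mps

    def test_unknown_type_raises(self):
        with pytest.raises(HetnetError):
            enumerate_metapaths({("drug", "t", "gene")}, "drug", "planet", 2)

    def test_deterministic_order(self):
        schema = {
            ("drug", "indication", "disease"),
            ("drug", "target", "gene"),
            ("gene", "association", "disease"),
        }
        a = enumerate_metapaths(schema, "drug", "disease", 3)
        b = enumerate_metapaths(schema, "drug", "disease", 3)
        assert a == b
        assert a == sorted(a, key=lambda m: (m.length, m.abbrev()))

    def test_matches_bfs_oracle_on_random_schemas(self, rng):
        for _ in range(10):
            net = make_random_hetnet(rng)
            types = sorted(net.node_types)
            src, tgt = types[0], types[-1]
            got = enumerate_metapaths(net.schema, src, tgt, 3)
            want = oracle_metapaths(net.schema, src, tgt, 3)
            assert {(m.node_types, m.edge_types) for m in got} == want


class TestDwpc:
    def test_single_path_closed_form(self, tiny_dgz):
        # one drug-gene-disease path; the gene's damping degree is 2
        assert dwpc(tiny_dgz, DGZ, "d1", "z1") == pytest.approx(
            2 ** -0.4, abs=1e-12
        )
        assert 2 ** -0.4 == pytest.approx(0.757858, abs=1e-6)

    def test_length_one_empty_product(self):
        net = Hetnet(
            nodes={"d": "drug", "z": "disease"},
            edges=[("d", "indication", "z")],
        )
        m = Metapath(("drug", "disease"), ("indication",))
        assert dwpc(net, m, "d", "z") == 1.0

    def test_no_path_is_zero(self, tiny_dgz):
        net = Hetnet(nodes=dict(tiny_dgz.nodes), edges=[])
        assert dwpc(net, DGZ, "d1", "z1") == 0.0

    def test_endpoint_type_mismatch_raises(self, tiny_dgz):
        with pytest.raises(HetnetError):
            dwpc(tiny_dgz, DGZ, "g1", "z1")

    def test_matches_dfs_oracle_on_random_graphs(self, rng):
        checked = 0
        for _ in range(8):
            net = make_random_hetnet(rng, n_nodes=15)
            types = sorted(net.node_types)
            for mp in enumerate_metapaths(net.schema, types[0], types[-1], 3)[:4]:
                for s in net.node_ids_of_type(types[0])[:3]:
                    for t in net.node_ids_of_type(types[-1])[:3]:
                        assert dwpc(net, mp, s, t) == pytest.approx(
                            oracle_dwpc(net, mp, s, t), abs=1e-9
                        )
                        checked += 1
        assert checked > 20

    def test_walk_semantics_counts_backtracking(self):
        # two genes hanging off one drug-disease pair, plus a drug-drug edge
        # creating a backtracking walk for the 3-hop metapath
        net = Hetnet(
            nodes={"d1": "drug", "d2": "drug", "g1": "gene", "z1": "disease"},
            edges=[
                ("d1", "target", "g1"),
                ("d2", "target", "g1"),
                ("g1", "association", "z1"),
            ],
        )
        m3 = Metapath(
            ("drug", "gene", "drug", "gene"),
            ("target", "target", "target"),
        )
        # node-distinct: d1 -> g1 -> d2 -> g1 revisits g1, so zero paths
        assert dwpc(net, m3, "d1", "g1") == 0.0
        assert dwpc(net, m3, "d1", "g1", path_semantics="walks") > 0.0

    def test_monotone_in_damping(self, tiny_dgz):
        values = [dwpc(tiny_dgz, DGZ, "d1", "z1", damping=w) for w in (0.2, 0.4, 0.8)]
        assert values[0] > values[1] > values[2]

    def test_permutation_invariance(self, rng):
        net = make_random_hetnet(rng, n_nodes=12)
        ids = list(net.nodes)
        perm = {old: f"m{idx:03d}" for idx, old in enumerate(rng.permutation(ids))}
        relabeled = Hetnet(
            nodes={perm[n]: t for n, t in net.nodes.items()},
            edges=[(perm[s], e, perm[t]) for s, e, t in net.edges],
        )
        types = sorted(net.node_types)
        for mp in enumerate_metapaths(net.schema, types[0], types[-1], 3)[:3]:
            for s in net.node_ids_of_type(types[0])[:3]:
                for t in net.node_ids_of_type(types[-1])[:3]:
                    assert dwpc(net, mp, s, t) == pytest.approx(
                        dwpc(relabeled, mp, perm[s], perm[t]), abs=1e-12
                    )

    def test_zero_law_removing_edge_type(self, tiny_dgz):
        stripped = Hetnet(
            nodes=dict(tiny_dgz.nodes),
            edges=[e for e in tiny_dgz.edges if e[1] != "association"],
        )
        assert dwpc(stripped, DGZ, "d1", "z1") == 0.0


class TestAllPairs:
    def test_no_first_edge_type_all_zero(self, tiny_dgz):
        net = Hetnet(
            nodes=dict(tiny_dgz.nodes),
            edges=[("g1", "association", "z1")],
        )
        mat = dwpc_all_pairs(net, DGZ)
        assert (mat.to_numpy() == 0).all()

    def test_one_by_one_matches_scalar(self, tiny_dgz):
        mat = dwpc_all_pairs(tiny_dgz, DGZ)
        assert mat.shape == (1, 1)
        assert mat.loc["d1", "z1"] == dwpc(tiny_dgz, DGZ, "d1", "z1")

    @pytest.mark.parametrize("semantics", ["paths", "walks"])
    def test_matrix_matches_scalar_elementwise(self, rng, semantics):
        net = make_random_hetnet(rng, n_nodes=14)
        types = sorted(net.node_types)
        for mp in enumerate_metapaths(net.schema, types[0], types[-1], 3)[:3]:
            mat = dwpc_all_pairs(net, mp, path_semantics=semantics)
            for s in mat.index:
                for t in mat.columns:
                    assert mat.loc[s, t] == pytest.approx(
                        dwpc(net, mp, s, t, path_semantics=semantics), abs=1e-9
                    )


class TestPrior:
    def test_no_indication_degree_is_zero(self):
        net = Hetnet(
            nodes={"d": "drug", "z": "disease"},
            edges=[("d", "contraindication", "z")],
        )
        assert prior_feature(net, "d", "z") == 0.0

    def test_single_indication_pair_is_one(self):
        net = Hetnet(
            nodes={"d": "drug", "z": "disease"},
            edges=[("d", "indication", "z")],
        )
        assert prior_feature(net, "d", "z") == 1.0

    def test_matches_degree_product_formula(self, rng):
        net = make_random_hetnet(
            rng, n_nodes=20, edge_types=("indication", "other")
        )
        n_ind = sum(1 for _, e, _ in net.edges if e == "indication")
        if n_ind == 0:
            pytest.skip("no indication edges drawn")
        for d in net.node_ids_of_type(sorted(net.node_types)[0])[:5]:
            for z in net.node_ids_of_type(sorted(net.node_types)[-1])[:5]:
                want = min(
                    1.0,
                    net.degree(d, "indication")
                    * net.degree(z, "indication")
                    / n_ind**2,
                )
                assert prior_feature(net, d, z) == pytest.approx(want)


class TestFeatureTable:
    def test_columns_and_index(self):
        net = Hetnet(
            nodes={"d": "drug", "g": "gene", "z": "disease"},
            edges=[
                ("d", "target", "g"),
                ("g", "association", "z"),
                ("d", "indication", "z"),
            ],
        )
        table = build_feature_table(net, max_length=2)
        assert "prior" in table.columns
        # the bare indication metapath is excluded (it is the label edge)
        assert "drug:indication:disease" not in table.columns
        assert DGZ.abbrev() in table.columns
        assert table.index.names == ["drug_id", "disease_id"]
        assert (table.to_numpy() >= 0).all()
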