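"""Friend-network construction, partner tables and graph exports."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest

from regomax.graph_core import DirectedNetwork, build_google_matrix
from regomax.reduced_matrix import reduce
from regomax.reduced_network import (
    build_friend_network,
    export_graph,
    friend_scores,
    import_edge_tsv,
    top_partners,
)
from regomax.synthetic_data import GroupSpec, SyntheticConfig, generate


@pytest.fixture(scope="module")
def synthetic_rgm():
    """12-node reduced matrix over two planted groups on a background."""
    cfg = SyntheticConfig(
        n_background=120,
        groups=[GroupSpec("cancer", 6, 0.10, 0.05), GroupSpec("drug", 6, 0.05, 0.08)],
        hub_count=2,
        dangling_fraction=0.0,
        seed=21,
    )
    net, cats = generate(cfg)
    subset = sorted(n for n, c in cats.items() if c in ("cancer", "drug"))
    rgm = reduce(build_google_matrix(net), subset, method="spectral")
    return rgm, cats


class TestFriendScores:
    def test_single_candidate_returned_regardless_of_score(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        out = friend_scores(rgm, rgm.subset[0], [rgm.subset[1]])
        assert [c for c, _ in out] == [rgm.subset[1]]

    def test_empty_candidate_set(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        assert friend_scores(rgm, rgm.subset[0], []) == []

    def test_top2_matches_exhaustive_column_maximum(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        M = rgm.G_rr + rgm.G_qrnd
        for from_node in rgm.subset[:4]:
            j = rgm.index_of(from_node)
            cands = [c for c in rgm.subset if c != from_node]
            ranked = friend_scores(rgm, from_node, cands)
            brute = sorted(((float(M[rgm.index_of(c), j]), c) for c in cands), reverse=True)
            assert {c for c, _ in ranked[:2]} == {c for _, c in brute[:2]}
            scores = [s for _, s in ranked]
            assert scores == sorted(scores, reverse=True)

    def test_equal_scores_tie_broken_by_local_pagerank(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        local_k = rgm.local_pagerank_index()
        # degenerate scoring: force all-equal scores via a zero matrix clone
        import regomax.reduced_network as rn

        class FlatRGM:
            subset = rgm.subset
            G_rr = np.zeros_like(rgm.G_rr)
            G_qr = np.zeros_like(rgm.G_qr)
            G_qrnd = np.zeros_like(rgm.G_qr)
            restricted_adjacency = rgm.restricted_adjacency
            index_of = rgm.index_of
            local_pagerank_index = rgm.local_pagerank_index

        out = rn.friend_scores(FlatRGM(), rgm.subset[0], list(rgm.subset[1:]))
        ks = [local_k[c] for c, _ in out]
        assert ks == sorted(ks)

    def test_self_in_candidates_rejected(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        with pytest.raises(ValueError):
            friend_scores(rgm, rgm.subset[0], [rgm.subset[0]])


class TestBuildFriendNetwork:
    def test_zero_friends_gives_seeds_only(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        seeds = [n for n in rgm.subset if cats[n] == "cancer"][:2]
        fn = build_friend_network(
            rgm, seeds, cats, "cancer", attach_categories=[], n_friends=0
        )
        assert sorted(fn.node_ids()) == sorted(seeds)
        assert fn.edges == []

    def test_star_dominated_matrix_fixpoint_after_first_iteration(self):
        # one planted node dominating every column: all seeds point to it
        ids = [f"g{i}" for i in range(6)] + [f"b{i}" for i in range(40)]
        rng = np.random.default_rng(8)
        links = set()
        for i in range(1, 40):
            links.add((f"b{i}", f"b{rng.integers(0, i)}"))
        for i in range(6):
            links.add((f"g{i}", "g0")) if i else None
            links.add((f"g{i}", f"b{i}"))
            links.add((f"b{i + 6}", f"g{i}"))
        net = DirectedNetwork(ids, links)
        subset = [f"g{i}" for i in range(6)]
        rgm = reduce(build_google_matrix(net), subset, method="spectral")
        cats = {n: "g" for n in subset}
        fn = build_friend_network(rgm, ["g1", "g2"], cats, "g", n_friends=1)
        scores = {
            n: friend_scores(rgm, n, [c for c in subset if c != n])[0][0]
            for n in ("g1", "g2")
        }
        assert all(v == "g0" for v in scores.values())  # exhaustive-score check
        assert {e.target for e in fn.edges if e.source in ("g1", "g2")} == {"g0"}
        # growth stops quickly: after the dominant node and at most one friend
        # of its own, no new nodes appear (edges to existing nodes may still
        # be recorded by the last expansion wave)
        assert max(n.iteration_added for n in fn.nodes) <= 2
        assert len(fn.primary_nodes()) <= 4

    def test_expansion_is_breadth_first_and_iterations_contiguous(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        seeds = [n for n in rgm.subset if cats[n] == "cancer"][:2]
        fn = build_friend_network(rgm, seeds, cats, "cancer",
                                  attach_categories=["drug"], n_friends=2, n_attach=1)
        iters = sorted({n.iteration_added for n in fn.nodes if n.role == "expanded"})
        assert iters == list(range(1, len(iters) + 1))
        # every non-seed primary node was added by an edge from an earlier node
        for n in fn.nodes:
            if n.role == "expanded":
                parents = [e for e in fn.edges if e.target == n.id and e.iteration == n.iteration_added]
                assert parents

    def test_attached_nodes_are_never_expanded(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        seeds = [n for n in rgm.subset if cats[n] == "cancer"][:2]
        fn = build_friend_network(rgm, seeds, cats, "cancer",
                                  attach_categories=["drug"], n_attach=2)
        attached = {n.id for n in fn.nodes if n.role == "attached"}
        assert attached  # drugs were attached
        assert not [e for e in fn.edges if e.source in attached]

    def test_hidden_edges_have_zero_restricted_adjacency(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        seeds = [n for n in rgm.subset if cats[n] == "cancer"][:3]
        fn = build_friend_network(rgm, seeds, cats, "cancer", attach_categories=["drug"])
        for e in fn.edges:
            i, j = rgm.index_of(e.target), rgm.index_of(e.source)
            if e.kind == "hidden":
                assert not rgm.restricted_adjacency[i, j]
            else:
                assert rgm.restricted_adjacency[i, j]

    def test_bad_seed_raises(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        with pytest.raises(ValueError):
            build_friend_network(rgm, ["ghost"], cats, "cancer")
        drug = [n for n in rgm.subset if cats[n] == "drug"][0]
        with pytest.raises(ValueError, match="category"):
            build_friend_network(rgm, [drug], cats, "cancer")


class TestTopPartners:
    def test_full_column_when_k_equals_candidates(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        cancers = [n for n in rgm.subset if cats[n] == "cancer"]
        drugs = [n for n in rgm.subset if cats[n] == "drug"]
        pt = top_partners(rgm, cancers[:1], drugs, k=len(drugs))
        assert len(pt.rows[cancers[0]]) == len(drugs)
        assert not pt.short_rows

    def test_matches_exhaustive_topk(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        cancers = [n for n in rgm.subset if cats[n] == "cancer"]
        drugs = [n for n in rgm.subset if cats[n] == "drug"]
        M = rgm.G_rr + rgm.G_qrnd
        pt = top_partners(rgm, cancers, drugs, k=3)
        for cr in cancers:
            j = rgm.index_of(cr)
            brute = sorted(((float(M[rgm.index_of(d), j]), d) for d in drugs), reverse=True)
            assert {p for p, _, _ in pt.rows[cr]} == {d for _, d in brute[:3]}
            scores = [s for _, s, _ in pt.rows[cr]]
            assert scores == sorted(scores, reverse=True)

    def test_oversized_k_flagged_short(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        cancers = [n for n in rgm.subset if cats[n] == "cancer"]
        drugs = [n for n in rgm.subset if cats[n] == "drug"]
        pt = top_partners(rgm, cancers[:1], drugs[:2], k=5)
        assert pt.short_rows == [cancers[0]]
        assert len(pt.rows[cancers[0]]) == 2

    def test_rows_cols_must_be_disjoint(self, synthetic_rgm):
        rgm, _ = synthetic_rgm
        with pytest.raises(ValueError, match="disjoint"):
            top_partners(rgm, rgm.subset[:2], rgm.subset[1:3])

    def test_both_score_variants_supported(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        cancers = [n for n in rgm.subset if cats[n] == "cancer"][:2]
        drugs = [n for n in rgm.subset if cats[n] == "drug"]
        a = top_partners(rgm, cancers, drugs, k=2, score="rr_plus_qrnd")
        b = top_partners(rgm, cancers, drugs, k=2, score="rr_plus_qr")
        assert set(a.rows) == set(b.rows)

    def test_planted_indirect_partner_ranked_first_and_hidden(self):
        cfg = SyntheticConfig(
            n_background=100,
            groups=[GroupSpec("cancer", 4, 0.05, 0.03), GroupSpec("drug", 4, 0.03, 0.05)],
            hub_count=1,
            planted_paths=[("cancer0", 1, "drug2")],
            dangling_fraction=0.0,
            seed=5,
        )
        net, cats = generate(cfg)
        subset = sorted(n for n, c in cats.items() if c in ("cancer", "drug"))
        rgm = reduce(build_google_matrix(net), subset, method="spectral")
        pt = top_partners(rgm, ["cancer0"], [n for n in subset if cats[n] == "drug"], k=3)
        partner, _, kind = pt.rows["cancer0"][0]
        assert partner == "drug2"
        assert kind == "hidden"


class TestExports:
    @pytest.fixture()
    def friend_net(self, synthetic_rgm):
        rgm, cats = synthetic_rgm
        seeds = [n for n in rgm.subset if cats[n] == "cancer"][:2]
        return build_friend_network(rgm, seeds, cats, "cancer", attach_categories=["drug"])

    def test_edge_tsv_round_trip_is_identity(self, friend_net, tmp_path):
        p = tmp_path / "fn.tsv"
        export_graph(friend_net, p, format="edge-tsv")
        back = import_edge_tsv(p)
        assert back.nodes == friend_net.nodes
        assert back.edges == friend_net.edges
        assert back.seeds == friend_net.seeds

    def test_exports_are_deterministic_bytes(self, friend_net, tmp_path):
        for fmt, name in (("edge-tsv", "a"), ("graphml", "b"), ("dot", "c")):
            p1, p2 = tmp_path / f"{name}1", tmp_path / f"{name}2"
            export_graph(friend_net, p1, format=fmt)
            export_graph(friend_net, p2, format=fmt)
            assert p1.read_bytes() == p2.read_bytes()

    def test_graphml_well_formed_with_attributes(self, friend_net, tmp_path):
        p = tmp_path / "fn.graphml"
        export_graph(friend_net, p, format="graphml")
        root = ET.parse(p).getroot()
        ns = "{http://graphml.graphdrawing.org/xmlns}"
        assert root.tag == f"{ns}graphml"
        graph = root.find(f"{ns}graph")
        nodes = graph.findall(f"{ns}node")
        edges = graph.findall(f"{ns}edge")
        assert len(nodes) == len(friend_net.nodes)
        assert len(edges) == len(friend_net.edges)
        keys = {k.get("attr.name") for k in root.findall(f"{ns}key")}
        assert {"category", "iteration", "kind", "weight"} <= keys

    def test_empty_network_exports_header_only(self, tmp_path):
        from regomax.reduced_network import FriendNetwork

        empty = FriendNetwork(nodes=[], edges=[], seeds=[])
        p = tmp_path / "empty.tsv"
        export_graph(empty, p, format="edge-tsv")
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("record")
        assert import_edge_tsv(p).nodes == []

    def test_unknown_format_rejected(self, friend_net, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_graph(friend_net, tmp_path / "x", format="svg")
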