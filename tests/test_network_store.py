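"""Network data model, TSV round trips and Table-style summaries."""

import numpy as np
import pytest

import gwgen as g
from gwgen.network import (
    EDGE_TYPES,
    GWGEN,
    Edge,
    Node,
    NetworkValidationError,
    load_network,
    summarize,
    write_network,
)
from .conftest import write_tiny_files


class TestLoad:
    def test_minimal_candidate(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path,
            [("A", "B", "TF-gene"), ("C", "B", "miRNA-gene")],
            [("A", "TF"), ("B", "gene"), ("C", "miRNA")],
        )
        net = load_network(ep, rp)
        assert len(net.nodes) == 3
        assert len(net.edges) == 2
        assert net.status == "candidate"

    def test_role_etype_mismatch_names_edge_index(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path,
            [("A", "B", "TF-gene"), ("C", "B", "miRNA-gene"),
             ("B", "A", "TF-gene")],
            [("A", "TF"), ("B", "gene"), ("C", "miRNA")],
        )
        with pytest.raises(NetworkValidationError, match="edge 3"):
            load_network(ep, rp)

    def test_unknown_role_names_offender(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path, [("A", "B", "TF-gene")],
            [("A", "TF"), ("B", "enhancer")],
        )
        with pytest.raises(NetworkValidationError, match="B"):
            load_network(ep, rp)

    def test_orphan_edge_lists_missing_ids(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path, [("A", "Z", "TF-gene")], [("A", "TF")]
        )
        with pytest.raises(NetworkValidationError, match="Z"):
            load_network(ep, rp)

    def test_mixed_weight_presence_rejected(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path,
            [("A", "B", "TF-gene", "0.5"), ("C", "B", "miRNA-gene", "")],
            [("A", "TF"), ("B", "gene"), ("C", "miRNA")],
            weighted=True,
        )
        with pytest.raises(NetworkValidationError, match="mixed"):
            load_network(ep, rp)

    def test_duplicate_edges_collapse_with_warning(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path,
            [("A", "B", "TF-gene"), ("A", "B", "TF-gene")],
            [("A", "TF"), ("B", "gene")],
        )
        with pytest.warns(UserWarning, match="duplicate"):
            net = load_network(ep, rp)
        assert len(net.edges) == 1

    def test_self_loop_rejected(self, tmp_path):
        ep, rp = write_tiny_files(
            tmp_path, [("A", "A", "PPI")], [("A", "protein")]
        )
        with pytest.raises(NetworkValidationError, match="self-loop"):
            load_network(ep, rp)

    @pytest.mark.parametrize(
        "edge_rows, role_rows",
        [
            ([("A", "B", "gene-TF")], [("A", "gene"), ("B", "TF")]),
            ([("C", "B", "miRNA-gene", "0.3")],
             [("C", "miRNA"), ("B", "gene")]),  # positive repression weight
            ([("A", "B", "lncRNA-gene")], [("A", "miRNA"), ("B", "gene")]),
        ],
    )
    def test_malformed_files_rejected(self, tmp_path, edge_rows, role_rows):
        weighted = any(len(r) == 4 for r in edge_rows)
        ep, rp = write_tiny_files(tmp_path, edge_rows, role_rows,
                                  weighted=weighted)
        with pytest.raises(NetworkValidationError):
            load_network(ep, rp)


class TestRoundTrip:
    def test_candidate_round_trip(self, tiny_candidate, tmp_path):
        ep = write_network(tiny_candidate, tmp_path / "net.tsv")
        assert load_network(ep, tmp_path / "net.roles.tsv") == tiny_candidate

    def test_real_round_trip_preserves_signs(self, tiny_nodes, tmp_path):
        real = GWGEN(
            nodes=tiny_nodes,
            edges=[Edge("A", "B", "TF-gene", 1.5),
                   Edge("C", "B", "miRNA-gene", -0.25)],
            status="real",
        )
        ep = write_network(real, tmp_path / "net.tsv")
        back = load_network(ep, tmp_path / "net.roles.tsv")
        assert back == real
        e = next(x for x in back.edges if x.etype == "miRNA-gene")
        assert e.weight == -0.25
        assert e.sign_constraint == "nonpositive"

    def test_core_status_survives_round_trip(self, tiny_nodes, tmp_path):
        core = GWGEN(
            nodes=tiny_nodes,
            edges=[Edge("A", "B", "TF-gene", 2.0)],
            status="core",
        )
        ep = write_network(core, tmp_path / "core.tsv")
        assert load_network(ep, tmp_path / "core.roles.tsv").status == "core"

    def test_generated_network_round_trip_and_byte_stability(
        self, truth_noisefree, tmp_path
    ):
        net = truth_noisefree.network
        p1 = write_network(net, tmp_path / "a.tsv")
        p2 = write_network(net, tmp_path / "b.tsv", tmp_path / "b.roles.tsv")
        assert (tmp_path / "a.tsv").read_bytes().split(b"\n", 2)[2] == (
            tmp_path / "b.tsv"
        ).read_bytes().split(b"\n", 2)[2]
        back = load_network(p1, tmp_path / "a.roles.tsv")
        assert back == net


class TestSummarize:
    def test_empty_network_all_zero(self):
        counts = summarize(GWGEN(nodes={}, edges=[], status="candidate"))
        assert (counts == 0).all()

    def test_three_node_example(self, tiny_candidate):
        counts = summarize(tiny_candidate)
        assert counts["TFs"] == 1
        assert counts["miRNAs"] == 1
        assert counts["TF-gene"] == 1
        assert counts["miRNA-gene"] == 1
        assert counts["Total Nodes"] == 3
        assert counts["Total Edges"] == 2

    def test_totals_are_additive_and_match_brute_force(self, truth_noisefree):
        net = truth_noisefree.network
        counts = summarize(net)
        node_rows = ["TFs", "lncRNAs", "miRNAs", "Receptors", "Proteins", "Genes"]
        edge_rows = [r for r in counts.index
                     if r in EDGE_TYPES or r == "PPIs"]
        assert counts["Total Nodes"] == sum(counts[r] for r in node_rows)
        assert counts["Total Edges"] == sum(counts[r] for r in edge_rows)
        # independent recount straight off the edge objects
        brute = {}
        for e in net.edges:
            brute[e.etype] = brute.get(e.etype, 0) + 1
        assert counts["PPIs"] == brute.get("PPI", 0)
        for etype in EDGE_TYPES:
            if etype == "PPI":
                continue
            assert counts[etype] == brute.get(etype, 0)


class TestRoundTripProperty:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _random_network(draw_weights, rng_seed):
        rng = np.random.default_rng(rng_seed)
        roles = ["TF", "receptor", "protein", "gene", "lncRNA", "miRNA"]
        nodes = {}
        for i, role in enumerate(rng.choice(roles, size=8)):
            nodes[f"n{i}"] = Node(f"n{i}", str(role))
        edges = []
        seen = set()
        by_role = {}
        for n in nodes.values():
            by_role.setdefault(n.role, []).append(n.id)
        prot = sum((by_role.get(r, []) for r in ("TF", "receptor", "protein")),
                   [])
        pools = {
            "PPI": (prot, prot), "TF-gene": (by_role.get("TF", []),
                                             by_role.get("gene", [])),
            "miRNA-gene": (by_role.get("miRNA", []), by_role.get("gene", [])),
            "lncRNA-miRNA": (by_role.get("lncRNA", []),
                             by_role.get("miRNA", [])),
        }
        for etype, (srcs, tgts) in pools.items():
            for s in srcs:
                for t in tgts:
                    if s == t or (s, t, etype) in seen or rng.random() < 0.5:
                        continue
                    seen.add((s, t, etype))
                    w = None
                    if draw_weights:
                        w = float(rng.uniform(0.1, 2.0))
                        if etype.startswith("miRNA"):
                            w = -w
                    edges.append(Edge(s, t, etype, w))
        status = "real" if draw_weights else "candidate"
        return GWGEN(nodes=nodes, edges=edges, status=status)

    @given(st.integers(0, 2**31 - 1), st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_any_valid_network_round_trips(self, rng_seed, weighted):
        import tempfile
        from pathlib import Path

        net = self._random_network(weighted, rng_seed)
        with tempfile.TemporaryDirectory() as d:
            ep = write_network(net, Path(d) / "n.tsv")
            back = load_network(ep, Path(d) / "n.roles.tsv")
        assert back == net


class TestInvariants:
    def test_real_network_requires_weights(self, tiny_nodes):
        with pytest.raises(NetworkValidationError, match="no weight"):
            GWGEN(nodes=tiny_nodes, edges=[Edge("A", "B", "TF-gene")],
                  status="real")

    def test_unknown_role_and_empty_id_rejected(self):
        with pytest.raises(NetworkValidationError):
            Node("X", "kinase")
        with pytest.raises(NetworkValidationError):
            Node("", "gene")

    def test_sign_constraint_follows_edge_type(self):
        assert Edge("a", "b", "miRNA-gene").sign_constraint == "nonpositive"
        assert Edge("a", "b", "TF-gene").sign_constraint == "free"
        assert Edge("a", "b", "PPI").sign_constraint == "free"
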