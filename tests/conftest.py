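import numpy as np
import pytest

import gwgen as g
from gwgen.network import GWGEN, Edge, Node


def as_candidate(network: GWGEN) -> GWGEN:
    """Strip weights from a real network to get its candidate skeleton."""
    return GWGEN(
        nodes=dict(network.nodes),
        edges=[Edge(e.source, e.target, e.etype) for e in network.edges],
        status="candidate",
    )


@pytest.fixture(scope="session")
def truth_noisefree():
    return g.generate_ground_truth(30, 15, 5, 5, avg_degree=3.0, seed=1,
                                   noise_sd=0.0)


@pytest.fixture(scope="session")
def data_noisefree(truth_noisefree):
    return g.generate_expression(truth_noisefree, "early", 200, seed=11)


@pytest.fixture(scope="session")
def truth_noisy():
    return g.generate_ground_truth(30, 15, 5, 5, avg_degree=3.0, seed=1,
                                   noise_sd=0.1)


@pytest.fixture(scope="session")
def data_noisy(truth_noisy):
    return g.generate_expression(truth_noisy, "early", 150, seed=21)


@pytest.fixture()
def tiny_nodes():
    return {
        "A": Node("A", "TF"),
        "B": Node("B", "gene"),
        "C": Node("C", "miRNA"),
    }


@pytest.fixture()
def tiny_candidate(tiny_nodes):
    return GWGEN(
        nodes=tiny_nodes,
        edges=[Edge("A", "B", "TF-gene"), Edge("C", "B", "miRNA-gene")],
        status="candidate",
    )


def write_tiny_files(tmp_path, edge_rows, role_rows, weighted=False):
    """Write raw edge/role TSVs from row tuples; returns the two paths."""
    edge_path = tmp_path / "edges.tsv"
    roles_path = tmp_path / "roles.tsv"
    header = "source\ttarget\tetype" + ("\tweight" if weighted else "")
    edge_path.write_text(
        "\n".join([header] + ["\t".join(map(str, r)) for r in edge_rows]) + "\n"
    )
    roles_path.write_text(
        "\n".join(["id\trole"] + ["\t".join(r) for r in role_rows]) + "\n"
    )
    return edge_path, roles_path
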