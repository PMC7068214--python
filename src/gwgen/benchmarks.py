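"""Benchmark constructors used by the validation suite.

These build controlled single-node regression problems and pure-noise
candidate networks with known answers, for exercising the order-selection
search, the permutation test's null calibration, and related statistical
checks outside of a full simulated network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .identify import RegressionProblem
from .network import GWGEN, Edge, Node
from .simulate import ExpressionDataset

__all__ = ["random_node_problem", "pure_noise_gene_network"]


def random_node_problem(
    rng: np.random.Generator,
    noise_sd: float = 0.1,
    n_samples: int = 100,
    max_candidates: int = 8,
) -> tuple[RegressionProblem, set[tuple[str, str]]]:
    """One random gene-type regression problem with a known true support.

    Candidate regulators are independent Uniform(1, 3) features; a random
    subset carries true abilities (magnitude Uniform(0.3, 1), random sign)
    while the rest are decoys, including up to two sign-constrained
    miRNA-type decoy columns.  Returns the problem and the true support.
    """
    h = int(rng.integers(2, max_candidates + 1))
    k_true = int(rng.integers(1, h + 1))
    n_mi = int(rng.integers(0, min(2, h - k_true) + 1))
    x = rng.uniform(1, 3, size=(n_samples, h))
    w = rng.uniform(0.3, 1.0, size=k_true) * rng.choice([-1.0, 1.0], size=k_true)
    beta = rng.uniform(1, 3)
    y = x[:, :k_true] @ w + beta
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n_samples)
    ids = [(f"R{i:02d}", "TF-gene") for i in range(h - n_mi)]
    ids += [(f"R{i:02d}", "miRNA-gene") for i in range(h - n_mi, h)]
    product = np.array([et.startswith("miRNA") for _, et in ids])
    problem = RegressionProblem(
        node_id="node",
        node_class="gene",
        regressor_ids=ids,
        regulator_values=x,
        response=y,
        product_mask=product,
        constraint_mask=np.append(product, False),
    )
    return problem, {ids[i] for i in range(k_true)}


def pure_noise_gene_network(
    n_nodes: int,
    n_tfs: int = 20,
    candidates_per_node: int = 4,
    n_samples: int = 100,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[GWGEN, ExpressionDataset, list[str]]:
    """Candidate network whose gene responses are independent of every regulator.

    TF features are Uniform(1, 3); each gene's expression is constant plus
    Gaussian noise, with ``candidates_per_node`` randomly assigned TF
    candidates.  Under this exchangeable null, a permutation AIC test should
    flag each gene with probability 1/(B+1).  Returns the network, the
    dataset, and the gene ids.
    """
    rng = np.random.default_rng(seed)
    tf_ids = [f"T{i:03d}" for i in range(n_tfs)]
    nodes = {t: Node(t, "TF") for t in tf_ids}
    rows: dict[str, np.ndarray] = {t: rng.uniform(1, 3, n_samples) for t in tf_ids}
    edges: list[Edge] = []
    gene_ids: list[str] = []
    for i in range(n_nodes):
        gid = f"N{i:04d}"
        gene_ids.append(gid)
        nodes[gid] = Node(gid, "gene")
        for t in rng.choice(tf_ids, size=candidates_per_node, replace=False):
            edges.append(Edge(str(t), gid, "TF-gene"))
        rows[gid] = 2.0 + rng.normal(0, noise_sd, n_samples)
    network = GWGEN(nodes=nodes, edges=edges, status="candidate")
    data = ExpressionDataset(
        values=pd.DataFrame(rows).T,
        feature_roles={nid: nodes[nid].role for nid in rows},
        stage="null",
    )
    return network, data, gene_ids
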