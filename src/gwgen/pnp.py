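"""Principal network projection (PNP): core-network extraction via SVD.

All estimated abilities of a real GWGEN are arranged in a zero-padded
network matrix ``P`` whose rows are the regulated nodes (proteins, then
genes, then lncRNAs, then miRNAs) and whose columns are the possible
regulators (one shared protein/TF column universe, then lncRNAs, then
miRNAs).  The thin SVD ``P = Q D R^T`` yields eigen expression fractions
``E_m = d_m^2 / sum d^2``; the smallest ``A`` whose cumulative fraction
reaches the energy threshold (0.85 by default) defines the principal
subspace, and each node's projection score is the 2-norm of its row's
projection onto the top-``A`` right singular vectors.  High-scoring nodes
per role form the core GWGEN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GWGEN, Edge

__all__ = [
    "NetworkMatrix",
    "ProjectionResult",
    "CoreSelectionPolicy",
    "assemble_matrix",
    "project",
    "extract_core",
]


@dataclass
class NetworkMatrix:
    values: np.ndarray  # (I+J+K+T) x (U+V+W)
    row_index: list[str]  # proteins, genes, lncRNAs, miRNAs
    col_index: list[str]  # proteins/TFs, lncRNAs, miRNAs
    roles: dict[str, str]

    @property
    def row_pos(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.row_index)}

    @property
    def col_pos(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.col_index)}


@dataclass
class ProjectionResult:
    singular_values: np.ndarray  # descending
    fractions: np.ndarray  # eigen expression fractions E_m
    rank_A: int
    scores: dict[str, float]  # node id -> projection 2-norm
    threshold: float

    def score_table(self, roles: dict[str, str]) -> pd.DataFrame:
        rows = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        frame = pd.DataFrame(rows, columns=["node", "score"])
        frame["role"] = [roles[n] for n in frame["node"]]
        frame["rank"] = np.arange(1, len(frame) + 1)
        return frame[["node", "role", "score", "rank"]]

    def spectrum_table(self) -> pd.DataFrame:
        cum = np.cumsum(self.fractions)
        return pd.DataFrame(
            {
                "m": np.arange(1, len(self.singular_values) + 1),
                "singular_value": self.singular_values,
                "fraction": self.fractions,
                "cumulative": cum,
            }
        )


def assemble_matrix(real_network: GWGEN) -> NetworkMatrix:
    """Place every estimated ability of a real GWGEN into the matrix ``P``.

    Entry (row of regulated node, column of regulator) holds the edge
    weight; everything else is zero-padded.  The placement is lossless: the
    weighted edge set can be reconstructed from the nonzero entries.
    """
    if real_network.status not in ("real", "core"):
        raise ValueError("assemble_matrix expects a weighted (real/core) network")
    roles = {nid: n.role for nid, n in real_network.nodes.items()}
    proteins = real_network.protein_ids()
    genes = real_network.node_ids("gene")
    lncrnas = real_network.node_ids("lncRNA")
    mirnas = real_network.node_ids("miRNA")
    row_index = proteins + genes + lncrnas + mirnas
    col_index = proteins + lncrnas + mirnas
    rpos = {nid: i for i, nid in enumerate(row_index)}
    cpos = {nid: i for i, nid in enumerate(col_index)}
    values = np.zeros((len(row_index), len(col_index)))
    for e in real_network.edges:
        if e.source not in cpos:
            raise ValueError(
                f"edge regulator {e.source!r} has no matrix column (role "
                f"{roles.get(e.source)!r} cannot regulate)"
            )
        values[rpos[e.target], cpos[e.source]] = e.weight
    return NetworkMatrix(
        values=values, row_index=row_index, col_index=col_index, roles=roles
    )


def project(matrix: NetworkMatrix, threshold: float = 0.85) -> ProjectionResult:
    """SVD of ``P`` and per-node 2-norm projection scores.

    ``rank_A`` is the minimal number of leading components whose eigen
    expression fractions accumulate to at least ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    p = matrix.values
    total = float((p**2).sum())
    if total == 0.0:
        warnings.warn("all-zero network matrix: every projection score is 0",
                      stacklevel=2)
        k = min(p.shape)
        return ProjectionResult(
            singular_values=np.zeros(k),
            fractions=np.zeros(k),
            rank_A=0,
            scores={nid: 0.0 for nid in matrix.row_index},
            threshold=threshold,
        )
    _, d, vt = np.linalg.svd(p, full_matrices=False)
    fractions = d**2 / (d**2).sum()
    cum = np.cumsum(fractions)
    rank_a = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    rank_a = min(rank_a, len(d))
    proj = p @ vt[:rank_a].T  # N_R(omega, l) for l <= A
    norms = np.sqrt((proj**2).sum(axis=1))
    scores = {nid: float(norms[i]) for i, nid in enumerate(matrix.row_index)}
    return ProjectionResult(
        singular_values=d,
        fractions=fractions,
        rank_A=rank_a,
        scores=scores,
        threshold=threshold,
    )


@dataclass
class CoreSelectionPolicy:
    """How many nodes each role contributes to the core network.

    Explicit per-role quotas win over ``per_role_fraction`` (the fraction of
    each role's nodes kept, rounded up).  Quotas exceeding the available
    nodes of a role are clamped with a warning.
    """

    per_role_quota: dict[str, int] | None = None
    per_role_fraction: float = 0.3

    def quota(self, role: str, available: int) -> int:
        if self.per_role_quota is not None:
            q = self.per_role_quota.get(role, 0)
        else:
            q = int(np.ceil(self.per_role_fraction * available))
        if q > available:
            warnings.warn(
                f"quota {q} for role {role!r} exceeds available {available}; "
                "clamped", stacklevel=3,
            )
            q = available
        return q


def extract_core(
    real_network: GWGEN,
    result: ProjectionResult,
    policy: CoreSelectionPolicy | None = None,
) -> GWGEN:
    """Select top-scoring nodes per role and induce the core GWGEN."""
    policy = policy or CoreSelectionPolicy()
    missing = set(real_network.nodes) - set(result.scores)
    if missing:
        raise ValueError(
            "projection scores missing for nodes: " + ", ".join(sorted(missing))
        )
    selected: set[str] = set()
    by_role: dict[str, list[str]] = {}
    for nid, node in real_network.nodes.items():
        by_role.setdefault(node.role, []).append(nid)
    for role, ids in sorted(by_role.items()):
        q = policy.quota(role, len(ids))
        ranked = sorted(ids, key=lambda nid: (-result.scores[nid], nid))
        selected.update(ranked[:q])
    edges = [
        Edge(source=e.source, target=e.target, etype=e.etype, weight=e.weight)
        for e in real_network.edges
        if e.source in selected and e.target in selected
    ]
    nodes = {nid: real_network.nodes[nid] for nid in selected}
    return GWGEN(nodes=nodes, edges=edges, status="core", stage=real_network.stage)
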