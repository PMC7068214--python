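"""Typed molecular networks and their tab-separated on-disk format.

A GWGEN (genome-wide genetic and epigenetic network) is the union of a
protein-protein interaction network (PPIN) and the gene/lncRNA/miRNA
regulatory networks.  Nodes carry one of six roles; receptors and
transcription factors (TFs) are members of the protein universe, i.e. they
may take part in PPI edges and (TFs only) act as transcriptional regulators.

Edges are directed from the regulator to the regulated node.  For PPI edges
the source is the interaction partner *h* and the target is the protein *i*
whose expression model the interaction ability ``a_ih`` belongs to; the
ability of the reverse orientation is a separate edge.  Edges of the three
``miRNA-*`` types model post-transcriptional repression and carry a
nonpositive weight once estimated.

Networks progress through three statuses: ``candidate`` (database-mined or
simulated superset, no weights), ``real`` (AIC-pruned, every edge carries an
estimated ability) and ``core`` (projection-selected subnetwork of a real
network).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

__all__ = [
    "ROLES",
    "PROTEIN_ROLES",
    "EDGE_TYPES",
    "Node",
    "Edge",
    "GWGEN",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "summarize",
]

ROLES = ("receptor", "protein", "TF", "lncRNA", "miRNA", "gene")

#: roles that belong to the protein universe (may appear in PPI edges)
PROTEIN_ROLES = frozenset({"receptor", "protein", "TF"})

#: etype -> (allowed source roles, allowed target roles, sign constraint)
EDGE_TYPES: Mapping[str, tuple[frozenset, frozenset, str]] = {
    "PPI": (PROTEIN_ROLES, PROTEIN_ROLES, "free"),
    "TF-gene": (frozenset({"TF"}), frozenset({"gene"}), "free"),
    "TF-lncRNA": (frozenset({"TF"}), frozenset({"lncRNA"}), "free"),
    "TF-miRNA": (frozenset({"TF"}), frozenset({"miRNA"}), "free"),
    "lncRNA-gene": (frozenset({"lncRNA"}), frozenset({"gene"}), "free"),
    "lncRNA-lncRNA": (frozenset({"lncRNA"}), frozenset({"lncRNA"}), "free"),
    "lncRNA-miRNA": (frozenset({"lncRNA"}), frozenset({"miRNA"}), "free"),
    "miRNA-gene": (frozenset({"miRNA"}), frozenset({"gene"}), "nonpositive"),
    "miRNA-lncRNA": (frozenset({"miRNA"}), frozenset({"lncRNA"}), "nonpositive"),
    "miRNA-miRNA": (frozenset({"miRNA"}), frozenset({"miRNA"}), "nonpositive"),
}

STATUSES = ("candidate", "real", "core")

#: Table-1 style summary row labels.  A "Genes" row is included (unlike the
#: published table, which folds protein-coding genes into the protein rows)
#: so that "Total Nodes" is exactly the sum of the role rows.
SUMMARY_ROWS = (
    "TFs",
    "TF-gene",
    "TF-lncRNA",
    "TF-miRNA",
    "lncRNAs",
    "lncRNA-gene",
    "lncRNA-lncRNA",
    "lncRNA-miRNA",
    "miRNAs",
    "miRNA-gene",
    "miRNA-lncRNA",
    "miRNA-miRNA",
    "Receptors",
    "Proteins",
    "Genes",
    "PPIs",
    "Total Nodes",
    "Total Edges",
)


class NetworkValidationError(ValueError):
    """Raised when a network or network file violates a structural invariant."""


@dataclass(frozen=True)
class Node:
    id: str
    role: str

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be a nonempty string")
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"unknown role {self.role!r} for node {self.id!r}; "
                f"expected one of {sorted(ROLES)}"
            )

    @property
    def is_protein(self) -> bool:
        return self.role in PROTEIN_ROLES


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    etype: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.etype not in EDGE_TYPES:
            raise NetworkValidationError(
                f"unknown edge type {self.etype!r}; expected one of "
                f"{sorted(EDGE_TYPES)}"
            )

    @property
    def sign_constraint(self) -> str:
        """``nonpositive`` for miRNA repression edges, ``free`` otherwise."""
        return EDGE_TYPES[self.etype][2]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.etype)


@dataclass
class GWGEN:
    """A validated network with typed nodes and directed, typed edges."""

    nodes: dict[str, Node]
    edges: list[Edge]
    status: str = "candidate"
    stage: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.status not in STATUSES:
            raise NetworkValidationError(f"unknown status {self.status!r}")
        for nid, node in self.nodes.items():
            if nid != node.id:
                raise NetworkValidationError(
                    f"node map key {nid!r} does not match node id {node.id!r}"
                )
        seen: set[tuple[str, str, str]] = set()
        orphans: set[str] = set()
        for idx, e in enumerate(self.edges, start=1):
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    orphans.add(endpoint)
            if orphans:
                continue
            src_roles, tgt_roles, _ = EDGE_TYPES[e.etype]
            if (
                self.nodes[e.source].role not in src_roles
                or self.nodes[e.target].role not in tgt_roles
            ):
                raise NetworkValidationError(
                    f"role/etype mismatch at edge {idx}: "
                    f"({e.source}:{self.nodes[e.source].role}) -> "
                    f"({e.target}:{self.nodes[e.target].role}) as {e.etype}"
                )
            if e.source == e.target:
                raise NetworkValidationError(
                    f"self-loop at edge {idx} ({e.source}, {e.etype}); "
                    "self-interaction is undefined"
                )
            if e.key in seen:
                raise NetworkValidationError(
                    f"duplicate edge {e.key} at edge {idx}"
                )
            seen.add(e.key)
            if self.status in ("real", "core") and e.weight is None:
                raise NetworkValidationError(
                    f"{self.status} network edge {e.key} has no weight"
                )
            if (
                e.weight is not None
                and e.sign_constraint == "nonpositive"
                and e.weight > 0
            ):
                raise NetworkValidationError(
                    f"miRNA repression edge {e.key} has positive weight "
                    f"{e.weight}"
                )
        if orphans:
            raise NetworkValidationError(
                "edges reference missing nodes: " + ", ".join(sorted(orphans))
            )

    # -- accessors ------------------------------------------------------
    def node_ids(self, *roles: str) -> list[str]:
        """Sorted ids of nodes whose role is in ``roles`` (all if empty)."""
        if not roles:
            return sorted(self.nodes)
        return sorted(n.id for n in self.nodes.values() if n.role in roles)

    def protein_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.is_protein)

    def regulators_of(self, node_id: str) -> list[Edge]:
        """Incoming edges of ``node_id`` (its candidate or fitted regulators)."""
        return [e for e in self.edges if e.target == node_id]

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def copy(self) -> "GWGEN":
        return GWGEN(
            nodes=dict(self.nodes),
            edges=[replace(e) for e in self.edges],
            status=self.status,
            stage=self.stage,
        )

    def equals(self, other: "GWGEN", rel_tol: float = 1e-12) -> bool:
        """Equality up to edge ordering and small weight round-off."""
        if self.nodes != other.nodes or self.status != other.status:
            return False
        mine = {e.key: e.weight for e in self.edges}
        theirs = {e.key: e.weight for e in other.edges}
        if mine.keys() != theirs.keys():
            return False
        for k, w in mine.items():
            v = theirs[k]
            if w is None or v is None:
                if w is not v:
                    return False
            elif abs(w - v) > rel_tol * max(1.0, abs(w), abs(v)):
                return False
        return True

    def __eq__(self, other: object) -> bool:  # exact weights
        if not isinstance(other, GWGEN):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.status == other.status
            and {e.key: e.weight for e in self.edges}
            == {e.key: e.weight for e in other.edges}
        )


def _read_tsv(path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV with optional leading ``#key=value`` comment lines."""
    meta: dict[str, str] = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    frame = pd.read_csv(path, sep="\t", skiprows=skip, dtype={0: str},
                        float_precision="round_trip")
    return frame, meta


def load_network(
    edge_list_path: str | os.PathLike,
    node_roles_path: str | os.PathLike,
) -> GWGEN:
    """Load and validate a network from an edge-list TSV and a roles TSV.

    The edge list has columns ``source, target, etype`` and optionally
    ``weight``; the roles file has columns ``id, role``.  Weight presence
    determines the status (all weights -> real, none -> candidate); a
    ``#status=core`` comment line in the edge file marks a core network.
    Duplicate (source, target, etype) rows are collapsed with a warning.
    """
    roles, _ = _read_tsv(os.fspath(node_roles_path))
    required = {"id", "role"}
    if not required.issubset(roles.columns):
        raise NetworkValidationError(
            f"roles file must have columns {sorted(required)}, "
            f"got {list(roles.columns)}"
        )
    nodes: dict[str, Node] = {}
    for _, row in roles.iterrows():
        nid = str(row["id"])
        if nid in nodes:
            raise NetworkValidationError(f"duplicate node id {nid!r} in roles file")
        nodes[nid] = Node(id=nid, role=str(row["role"]))

    edges_df, meta = _read_tsv(os.fspath(edge_list_path))
    for col in ("source", "target", "etype"):
        if col not in edges_df.columns:
            raise NetworkValidationError(
                f"edge file must have columns source, target, etype; "
                f"got {list(edges_df.columns)}"
            )
    has_weight = "weight" in edges_df.columns
    edges: list[Edge] = []
    seen: set[tuple[str, str, str]] = set()
    n_weighted = 0
    for _, row in edges_df.iterrows():
        weight = None
        if has_weight and pd.notna(row["weight"]):
            weight = float(row["weight"])
            n_weighted += 1
        e = Edge(
            source=str(row["source"]),
            target=str(row["target"]),
            etype=str(row["etype"]),
            weight=weight,
        )
        if e.key in seen:
            warnings.warn(
                f"collapsing duplicate edge {e.key} in {edge_list_path}",
                stacklevel=2,
            )
            continue
        seen.add(e.key)
        edges.append(e)
    if 0 < n_weighted < len(edges):
        raise NetworkValidationError(
            f"mixed weight presence: {n_weighted} of {len(edges)} edges "
            "carry weights; a network is either fully weighted (real/core) "
            "or unweighted (candidate)"
        )
    if n_weighted and n_weighted == len(edges):
        status = meta.get("status", "real")
    else:
        status = meta.get("status", "candidate")
        if status in ("real", "core") and edges:
            raise NetworkValidationError(
                f"file declares status={status} but edges carry no weights"
            )
    return GWGEN(nodes=nodes, edges=edges, status=status, stage=meta.get("stage"))


def write_network(
    network: GWGEN,
    edge_list_path: str | os.PathLike,
    node_roles_path: str | os.PathLike | None = None,
) -> str:
    """Write a network as edge-list + roles TSVs; returns the edge path.

    Weights are written with ``repr`` so the round trip through
    :func:`load_network` reproduces them bit-exactly.  If
    ``node_roles_path`` is omitted it defaults to the edge path with a
    ``.roles.tsv`` suffix.
    """
    edge_path = os.fspath(edge_list_path)
    if node_roles_path is None:
        base = edge_path[:-4] if edge_path.endswith(".tsv") else edge_path
        node_roles_path = base + ".roles.tsv"
    weighted = network.status in ("real", "core")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write(f"#status={network.status}\n")
        if network.stage is not None:
            fh.write(f"#stage={network.stage}\n")
        header = "source\ttarget\tetype"
        fh.write(header + ("\tweight" if weighted else "") + "\n")
        for e in sorted(network.edges, key=lambda e: e.key):
            row = f"{e.source}\t{e.target}\t{e.etype}"
            if weighted:
                row += f"\t{e.weight!r}"
            fh.write(row + "\n")
    with open(os.fspath(node_roles_path), "w", encoding="utf-8") as fh:
        fh.write("id\trole\n")
        for nid in sorted(network.nodes):
            fh.write(f"{nid}\t{network.nodes[nid].role}\n")
    return edge_path


def summarize(network: GWGEN) -> pd.Series:
    """Per-role node counts and per-type edge counts, Table-1 style.

    ``Total Nodes`` equals the sum of the six role rows and ``Total Edges``
    the sum of the ten edge-type rows.
    """
    role_counts = {r: 0 for r in ROLES}
    for node in network.nodes.values():
        role_counts[node.role] += 1
    type_counts = {t: 0 for t in EDGE_TYPES}
    for e in network.edges:
        type_counts[e.etype] += 1
    values = {
        "TFs": role_counts["TF"],
        "TF-gene": type_counts["TF-gene"],
        "TF-lncRNA": type_counts["TF-lncRNA"],
        "TF-miRNA": type_counts["TF-miRNA"],
        "lncRNAs": role_counts["lncRNA"],
        "lncRNA-gene": type_counts["lncRNA-gene"],
        "lncRNA-lncRNA": type_counts["lncRNA-lncRNA"],
        "lncRNA-miRNA": type_counts["lncRNA-miRNA"],
        "miRNAs": role_counts["miRNA"],
        "miRNA-gene": type_counts["miRNA-gene"],
        "miRNA-lncRNA": type_counts["miRNA-lncRNA"],
        "miRNA-miRNA": type_counts["miRNA-miRNA"],
        "Receptors": role_counts["receptor"],
        "Proteins": role_counts["protein"],
        "Genes": role_counts["gene"],
        "PPIs": type_counts["PPI"],
        "Total Nodes": len(network.nodes),
        "Total Edges": len(network.edges),
    }
    return pd.Series([values[r] for r in SUMMARY_ROWS], index=list(SUMMARY_ROWS))
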