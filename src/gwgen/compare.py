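"""Cross-stage differential analysis of GWGENs.

Structural comparison is exact set algebra on node ids and on edge keys
(source, target, etype) - weights may differ between stages and are
reported, never used for membership.  Basal-level shifts between stages act
as the proxy for epigenetic modification (methylation, acetylation, ...):
the intercept of a node's model absorbs stage-specific offsets that the
regulatory terms cannot explain.  Shifts are standardized by a residual
bootstrap of the two stage fits and flagged above a configurable cutoff.

Over-representation of a node selection against user-supplied gene sets
(GMT) uses the one-sided hypergeometric tail with Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .identify import NodeModelFit, fit_constrained
from .network import GWGEN

__all__ = [
    "DifferentialReport",
    "BasalShiftReport",
    "diff_networks",
    "basal_shift_scores",
    "overrepresentation",
    "read_gmt",
]


@dataclass
class DifferentialReport:
    shared_nodes: set[str]
    unique_nodes_a: set[str]
    unique_nodes_b: set[str]
    shared_edges: set[tuple[str, str, str]]
    unique_edges_a: set[tuple[str, str, str]]
    unique_edges_b: set[tuple[str, str, str]]
    weights_a: dict[tuple[str, str, str], float | None]
    weights_b: dict[tuple[str, str, str], float | None]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.shared_edges | self.unique_edges_a | self.unique_edges_b):
            member = (
                "shared" if key in self.shared_edges
                else "a_only" if key in self.unique_edges_a
                else "b_only"
            )
            rows.append(
                (*key, member, self.weights_a.get(key), self.weights_b.get(key))
            )
        return pd.DataFrame(
            rows,
            columns=["source", "target", "etype", "membership",
                     "weight_a", "weight_b"],
        )


def diff_networks(a: GWGEN, b: GWGEN) -> DifferentialReport:
    """Exact structural difference of two networks (nodes and edge keys)."""
    na, nb = set(a.nodes), set(b.nodes)
    ea, eb = a.edge_keys(), b.edge_keys()
    return DifferentialReport(
        shared_nodes=na & nb,
        unique_nodes_a=na - nb,
        unique_nodes_b=nb - na,
        shared_edges=ea & eb,
        unique_edges_a=ea - eb,
        unique_edges_b=eb - ea,
        weights_a={e.key: e.weight for e in a.edges},
        weights_b={e.key: e.weight for e in b.edges},
    )


@dataclass
class BasalShiftReport:
    """Per-node basal-level comparison between two stages.

    ``table`` columns: node, basal_a, basal_b, delta (basal_b - basal_a),
    se (pooled bootstrap standard error; NaN when n_boot = 0) and score
    (|delta| / se).  ``flags`` lists (node, direction) for scores above the
    cutoff; ``only_in_a`` / ``only_in_b`` name nodes fitted in one stage only.
    """

    table: pd.DataFrame
    flags: list[tuple[str, str]]
    only_in_a: list[str]
    only_in_b: list[str]
    cutoff: float
    n_boot: int


def _bootstrap_basal_se(
    fit: NodeModelFit, n_boot: int, rng: np.random.Generator
) -> float:
    problem = fit.problem
    if problem is None:
        raise ValueError(f"fit for {fit.node_id} carries no problem (needed "
                         "for the residual bootstrap)")
    phi = problem.regressor_matrix
    theta = fit.coefficients
    fitted = phi @ theta
    resid = problem.response - fitted
    n = len(resid)
    basals = np.empty(n_boot)
    for b in range(n_boot):
        y_star = fitted + resid[rng.integers(0, n, size=n)]
        refit = fit_constrained(problem.with_response(y_star))
        basals[b] = refit.basal
    return float(basals.std(ddof=1))


def basal_shift_scores(
    fits_a: dict[str, NodeModelFit],
    fits_b: dict[str, NodeModelFit],
    n_boot: int = 100,
    seed: int = 0,
    cutoff: float = 2.0,
) -> BasalShiftReport:
    """Standardized basal-level shifts between two stages' node fits.

    With ``n_boot = 0`` the report degrades to the raw delta ranking and no
    node is flagged.
    """
    common = sorted(set(fits_a) & set(fits_b))
    only_a = sorted(set(fits_a) - set(fits_b))
    only_b = sorted(set(fits_b) - set(fits_a))
    rng = np.random.default_rng(seed)
    rows = []
    flags: list[tuple[str, str]] = []
    for nid in common:
        fa, fb = fits_a[nid], fits_b[nid]
        delta = fb.basal - fa.basal
        if n_boot > 0:
            se_a = _bootstrap_basal_se(fa, n_boot, rng)
            se_b = _bootstrap_basal_se(fb, n_boot, rng)
            se = float(np.hypot(se_a, se_b))
            if se > 0:
                score = abs(delta) / se
            else:
                score = 0.0 if delta == 0 else np.inf
            if score > cutoff:
                flags.append((nid, "up" if delta > 0 else "down"))
        else:
            se, score = np.nan, np.nan
        rows.append((nid, fa.basal, fb.basal, delta, se, score))
    table = pd.DataFrame(
        rows, columns=["node", "basal_a", "basal_b", "delta", "se", "score"]
    )
    sort_col = "score" if n_boot > 0 else "delta"
    table = table.sort_values(
        sort_col, key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
    return BasalShiftReport(
        table=table,
        flags=flags,
        only_in_a=only_a,
        only_in_b=only_b,
        cutoff=cutoff,
        n_boot=n_boot,
    )


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file (name, description, member ids...)."""
    sets: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {p for p in parts[2:] if p}
    return sets


def overrepresentation(
    core_nodes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    For each set, overlap ``k`` of the selection (size ``n``) with the set
    restricted to the universe (size ``m``) out of ``M`` universe nodes;
    p = P(X >= k) for X ~ Hypergeom(M, m, n).
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not core_nodes <= universe:
        raise ValueError("selection must be a subset of the universe")
    m_total = len(universe)
    n_sel = len(core_nodes)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        m = len(members)
        k = len(members & core_nodes)
        if m == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, m_total, m, n_sel))
        expected = n_sel * m / m_total
        rows.append((name, m, k, expected, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "expected", "p"]
    )
    if len(frame):
        frame["p_adj"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["p_adj"] = frame["p"]
    return frame.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
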