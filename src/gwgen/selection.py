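"""AIC-based system-order detection and false-positive pruning.

The per-node criterion is ``AIC = log(RSS/N) + 2*(order+1)/N`` where the
``+1`` counts the basal term.  The real order is the AIC minimizer over
regulator subsets; two search strategies are provided:

* ``greedy`` - fit the full constrained model, rank regressors by
  contribution-scaled coefficient magnitude (|estimate| * sd of the
  regressor column), and evaluate the nested prefix models of order 0..H;
* ``exhaustive`` - evaluate all 2^H subsets (H <= 15), used mainly as an
  oracle for the greedy path.

Ties in AIC are broken toward the smaller order.  Pruning a whole network
applies the search independently per node and assembles the surviving
regulators, refitted on the retained set, into the real GWGEN.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .identify import (
    NodeModelFit,
    RegressionProblem,
    build_problem,
    fit_constrained,
    truncate_problem,
)
from .network import GWGEN, Edge
from .simulate import ExpressionDataset

__all__ = ["OrderSearchResult", "PruneResult", "aic", "detect_order", "prune_network"]

_RSS_FLOOR = 1e-300


def aic(rss: float, n: int, order: int) -> float:
    """Akaike information criterion for a fitted node model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss < _RSS_FLOOR:
        warnings.warn("rss = 0 floored at 1e-300 (perfect fit)", stacklevel=2)
        rss = _RSS_FLOOR
    return math.log(rss / n) + 2.0 * (order + 1) / n


@dataclass
class OrderSearchResult:
    node_id: str
    aic_by_order: list[tuple[int, float]]
    selected_order: int
    retained_regulators: list[tuple[str, str]]
    final_fit: NodeModelFit

    @property
    def selected_aic(self) -> float:
        return dict(self.aic_by_order)[self.selected_order]


def _fit_aic(problem: RegressionProblem) -> tuple[NodeModelFit, float]:
    fit = fit_constrained(problem)
    # Perfect fits leave RSS at float-epsilon dust whose log differences would
    # swamp the order penalty; floor at the squared response round-off scale
    # so numerically-perfect fits tie and the penalty picks the smaller order.
    floor = (1e-9 * float(np.linalg.norm(problem.response))) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = aic(max(fit.rss, floor), fit.n_samples, fit.order)
    return fit, value


def detect_order(
    problem: RegressionProblem, strategy: str = "greedy"
) -> OrderSearchResult:
    """Select the AIC-minimizing regulator subset of one node."""
    if problem.order > problem.n_samples - 2:
        problem = truncate_problem(problem)
    h = problem.order
    if strategy == "greedy":
        return _detect_greedy(problem)
    if strategy == "exhaustive":
        if h > 15:
            raise ValueError(
                f"exhaustive search limited to order <= 15, got {h}"
            )
        return _detect_exhaustive(problem)
    raise ValueError(f"unknown strategy {strategy!r}")


def _detect_greedy(problem: RegressionProblem) -> OrderSearchResult:
    h = problem.order
    full_fit, _ = _fit_aic(problem)
    cols = problem.regressor_matrix[:, :-1]
    scale = cols.std(axis=0) if h else np.empty(0)
    score = np.abs(full_fit.coefficients[:-1]) * scale
    ranking = np.argsort(-score, kind="stable")

    best: tuple[float, int] | None = None
    path: list[tuple[int, float]] = []
    fits: list[NodeModelFit] = []
    for k in range(h + 1):
        sub = problem.subset(list(ranking[:k]))
        fit, value = _fit_aic(sub)
        path.append((k, value))
        fits.append(fit)
        if best is None or value < best[0] - 1e-12:
            best = (value, k)
    assert best is not None
    k = best[1]
    final = fits[k]
    return OrderSearchResult(
        node_id=problem.node_id,
        aic_by_order=path,
        selected_order=k,
        retained_regulators=list(final.problem.regressor_ids),
        final_fit=final,
    )


def _detect_exhaustive(problem: RegressionProblem) -> OrderSearchResult:
    h = problem.order
    best: tuple[float, tuple[int, ...]] | None = None
    best_fit: NodeModelFit | None = None
    best_by_size: dict[int, float] = {}
    # subsets enumerated by size then lexicographically: ties resolve toward
    # the smaller order, then the earlier subset, deterministically
    for k in range(h + 1):
        for combo in itertools.combinations(range(h), k):
            sub = problem.subset(list(combo))
            fit, value = _fit_aic(sub)
            if k not in best_by_size or value < best_by_size[k]:
                best_by_size[k] = value
            if best is None or value < best[0] - 1e-12:
                best = (value, combo)
                best_fit = fit
    assert best is not None and best_fit is not None
    return OrderSearchResult(
        node_id=problem.node_id,
        aic_by_order=sorted(best_by_size.items()),
        selected_order=len(best[1]),
        retained_regulators=list(best_fit.problem.regressor_ids),
        final_fit=best_fit,
    )


@dataclass
class PruneResult:
    """Real GWGEN plus the per-node order-search record behind it."""

    network: GWGEN
    results: dict[str, OrderSearchResult]

    def fits(self) -> dict[str, NodeModelFit]:
        return {nid: r.final_fit for nid, r in self.results.items()}


def prune_network(
    candidate: GWGEN,
    data: ExpressionDataset,
    strategy: str = "greedy",
) -> PruneResult:
    """Prune a candidate GWGEN into a real GWGEN, node by node.

    Each node's regulators are selected independently with
    :func:`detect_order`; the real network's edges are the union of the
    retained regulator sets, weighted by the refitted abilities.  A node
    whose search fails falls back to a basal-only model with a warning.
    """
    missing = sorted(set(candidate.nodes) - set(data.values.index))
    if missing:
        raise KeyError(
            "candidate nodes missing from expression data: " + ", ".join(missing)
        )
    results: dict[str, OrderSearchResult] = {}
    edges: list[Edge] = []
    for nid in sorted(candidate.nodes):
        problem = build_problem(nid, candidate, data)
        try:
            res = detect_order(problem, strategy=strategy)
        except Exception as exc:  # pragma: no cover - defensive fallback
            warnings.warn(
                f"order search failed for node {nid} ({exc}); "
                "falling back to basal-only model",
                stacklevel=2,
            )
            res = detect_order(problem.subset([]), strategy="greedy")
        results[nid] = res
        for (reg, etype) in res.retained_regulators:
            w = res.final_fit.estimates[(reg, etype)]
            edges.append(Edge(source=reg, target=nid, etype=etype, weight=w))
    real = GWGEN(
        nodes=dict(candidate.nodes),
        edges=edges,
        status="real",
        stage=data.stage,
    )
    return PruneResult(network=real, results=results)
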