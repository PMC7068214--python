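"""Per-node regression assembly and (constrained) least-squares fitting.

Each node's expression model is linear in its unknown abilities once the
regressor columns are formed from the data.  For a protein, every column is
the product of its own expression with a PPI partner's expression; for
genes, lncRNAs and miRNAs the TF and lncRNA columns are the raw regulator
series while the miRNA columns are products of the response with the miRNA
series (post-transcriptional repression acts multiplicatively on the
transcript).  The final all-ones column estimates the basal level.

miRNA-repression coefficients are constrained to be nonpositive; the fit is
a box-constrained least squares (ordinary least squares when no constraint
is active or present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import lsq_linear

from .network import GWGEN, PROTEIN_ROLES
from .simulate import ExpressionDataset

__all__ = ["RegressionProblem", "NodeModelFit", "build_problem",
           "truncate_problem", "fit_constrained"]

_BLOCK_ORDER = {"TF": 0, "PPI": 0, "lncRNA": 1, "miRNA": 2}
_RCOND = 1e-10  # singular values below _RCOND * sigma_max treated as zero


def _block(etype: str) -> int:
    return _BLOCK_ORDER[etype.split("-")[0]] if etype != "PPI" else 0


@dataclass
class RegressionProblem:
    """One node's least-squares problem in the model's block layout.

    ``regulator_values`` holds the raw regulator series so the design matrix
    can be rebuilt for a different response (product columns involve the
    response itself), which permutation testing and bootstrapping rely on.
    """

    node_id: str
    node_class: str  # protein | gene | lncRNA | miRNA
    regressor_ids: list[tuple[str, str]]  # (regulator id, etype), block order
    regulator_values: np.ndarray  # N x H raw regulator series
    response: np.ndarray  # length N
    product_mask: np.ndarray  # H bools: column is response * regulator
    constraint_mask: np.ndarray  # H+1 bools: nonpositive coefficient (basal False)
    truncated_from: int | None = None  # original order if pre-truncated

    @property
    def n_samples(self) -> int:
        return self.response.shape[0]

    @property
    def order(self) -> int:
        return len(self.regressor_ids)

    @property
    def regressor_matrix(self) -> np.ndarray:
        """N x (order+1) design matrix; the last column is all ones."""
        n = self.n_samples
        if self.order:
            cols = np.where(
                self.product_mask[None, :],
                self.regulator_values * self.response[:, None],
                self.regulator_values,
            )
        else:
            cols = np.empty((n, 0))
        return np.hstack([cols, np.ones((n, 1))])

    def with_response(self, response: np.ndarray) -> "RegressionProblem":
        """Same regulators, new response; product columns are rebuilt."""
        if response.shape != self.response.shape:
            raise ValueError("response length mismatch")
        return replace(self, response=np.asarray(response, dtype=float))

    def subset(self, indices: list[int]) -> "RegressionProblem":
        """Restrict to the given regressor columns (kept in block order)."""
        idx = sorted(indices)
        return replace(
            self,
            regressor_ids=[self.regressor_ids[i] for i in idx],
            regulator_values=self.regulator_values[:, idx],
            product_mask=self.product_mask[idx],
            constraint_mask=np.append(self.constraint_mask[idx], False),
            truncated_from=None,
        )


@dataclass
class NodeModelFit:
    node_id: str
    estimates: dict[tuple[str, str], float]  # (regulator id, etype) -> ability
    basal: float
    rss: float
    n_samples: int
    order: int
    fitted_under_constraint: bool
    problem: RegressionProblem | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> np.ndarray:
        """Abilities in the problem's column order, basal last."""
        if self.problem is None:
            raise ValueError("fit carries no problem reference")
        vals = [self.estimates[rid] for rid in self.problem.regressor_ids]
        return np.array(vals + [self.basal])


def build_problem(
    node_id: str,
    network: GWGEN,
    data: ExpressionDataset,
    max_order: int | None = None,
) -> RegressionProblem:
    """Assemble a node's regression problem from its candidate regulators.

    Columns are ordered TF/protein block, then lncRNA block, then miRNA
    block (basal last).  If the candidate order exceeds ``N - 2`` (or
    ``max_order``), the problem is pre-truncated to the regressors whose
    columns have the highest absolute Pearson correlation with the response,
    preserving block order; AIC pruning happens downstream.
    """
    if node_id not in network.nodes:
        raise KeyError(f"node {node_id!r} not in network")
    if node_id not in data.values.index:
        raise KeyError(f"node {node_id!r} not in expression data")
    role = network.nodes[node_id].role
    node_class = "protein" if role in PROTEIN_ROLES else role
    y = data.series(node_id)
    n = y.shape[0]

    regs = network.regulators_of(node_id)
    missing = sorted({e.source for e in regs} - set(data.values.index))
    if missing:
        raise KeyError(
            f"regulators of {node_id!r} missing from expression data: "
            + ", ".join(missing)
        )
    regs = sorted(regs, key=lambda e: (_block(e.etype), e.etype, e.source))
    reg_ids = [(e.source, e.etype) for e in regs]
    if reg_ids:
        rv = np.column_stack([data.series(e.source) for e in regs])
    else:
        rv = np.empty((n, 0))
    if node_class == "protein":
        product = np.ones(len(regs), dtype=bool)
        constrained = np.zeros(len(regs), dtype=bool)
    else:
        product = np.array([e.etype.startswith("miRNA") for e in regs], dtype=bool)
        constrained = product.copy()

    problem = RegressionProblem(
        node_id=node_id,
        node_class=node_class,
        regressor_ids=reg_ids,
        regulator_values=rv,
        response=y,
        product_mask=product,
        constraint_mask=np.append(constrained, False),
    )

    if max_order is not None and problem.order > max_order:
        problem = truncate_problem(problem, max_order)
    return problem


def truncate_problem(
    problem: RegressionProblem, max_order: int | None = None
) -> RegressionProblem:
    """Cap an over-parameterized problem at ``max_order`` regressors.

    Keeps the regressors whose assembled columns have the highest absolute
    Pearson correlation with the response (block order preserved).  The
    default cap is ``N - 2``, the largest order that leaves the least-squares
    problem well-posed with a basal term; downstream AIC pruning shrinks the
    model further.
    """
    cap = problem.n_samples - 2 if max_order is None else max_order
    cap = max(cap, 0)
    if problem.order <= cap:
        return problem
    y = problem.response
    cols = problem.regressor_matrix[:, :-1]
    yc = y - y.mean()
    cc = cols - cols.mean(axis=0)
    denom = np.sqrt((cc**2).sum(axis=0) * (yc**2).sum()) + 1e-300
    corr = np.abs(cc.T @ yc) / denom
    keep = np.argsort(-corr, kind="stable")[:cap]
    original = problem.order
    truncated = problem.subset(list(keep))
    truncated.truncated_from = original
    return truncated


def fit_constrained(problem: RegressionProblem) -> NodeModelFit:
    """Minimize 0.5 * ||Phi theta - y||^2 with nonpositivity on masked entries.

    When no sign constraint binds, the solution is the (minimum-norm on rank
    deficiency) ordinary least-squares estimate; otherwise the
    box-constrained problem is solved, trying the bounded-variable
    least-squares solver first.
    """
    phi = problem.regressor_matrix
    y = problem.response
    mask = problem.constraint_mask
    n, p = phi.shape

    theta, rank = _lstsq_minnorm(phi, y)
    if rank < p:
        warnings.warn(
            f"rank-deficient design for node {problem.node_id} "
            f"(rank {rank} < {p}); minimum-norm solution used",
            stacklevel=2,
        )
    under_constraint = False
    if mask.any() and np.any(theta[mask] > 0):
        under_constraint = True
        ub = np.where(mask, 0.0, np.inf)
        lb = np.full(p, -np.inf)
        method = "bvls" if (n >= p and rank == p) else "trf"
        res = lsq_linear(phi, y, bounds=(lb, ub), method=method,
                         tol=1e-14, max_iter=300)
        theta = res.x
    theta = np.where(mask, np.minimum(theta, 0.0), theta)

    resid = y - phi @ theta
    rss = float(resid @ resid)
    estimates = {
        rid: float(theta[i]) for i, rid in enumerate(problem.regressor_ids)
    }
    return NodeModelFit(
        node_id=problem.node_id,
        estimates=estimates,
        basal=float(theta[-1]),
        rss=rss,
        n_samples=n,
        order=problem.order,
        fitted_under_constraint=under_constraint,
        problem=problem,
    )


def _lstsq_minnorm(phi: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    theta, _, rank, _ = np.linalg.lstsq(phi, y, rcond=_RCOND)
    return theta, int(rank)
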