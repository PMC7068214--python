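"""Regression assembly and constrained least-squares estimation."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import gwgen as g
from gwgen.identify import RegressionProblem, build_problem, fit_constrained
from gwgen.network import GWGEN, Edge, Node
from gwgen.simulate import ExpressionDataset
from .conftest import as_candidate


def make_dataset(rows: dict, roles: dict, stage="s") -> ExpressionDataset:
    return ExpressionDataset(values=pd.DataFrame(rows).T,
                             feature_roles=roles, stage=stage)


def active_set_lsq(phi, y, mask):
    """Constrained LS oracle: enumerate active sets of the sign constraints.

    For each subset of masked coefficients pinned to zero, solve the reduced
    unconstrained problem and keep the best feasible solution.  Exponential,
    hence only for small problems in tests.
    """
    p = phi.shape[1]
    masked = [i for i in range(p) if mask[i]]
    best, best_obj = None, np.inf
    for active in itertools.chain.from_iterable(
        itertools.combinations(masked, r) for r in range(len(masked) + 1)
    ):
        free = [i for i in range(p) if i not in active]
        theta = np.zeros(p)
        sol, *_ = np.linalg.lstsq(phi[:, free], y, rcond=None)
        theta[free] = sol
        if any(theta[i] > 1e-10 for i in masked):
            continue
        obj = float(np.sum((phi @ theta - y) ** 2))
        if obj < best_obj - 1e-12:
            best, best_obj = theta, obj
    return best, best_obj


class TestBuildProblem:
    def test_gene_block_layout_and_mask(self):
        roles = {"T": "TF", "L": "lncRNA", "M": "miRNA", "G": "gene"}
        nodes = {k: Node(k, v) for k, v in roles.items()}
        net = GWGEN(
            nodes=nodes,
            edges=[Edge("T", "G", "TF-gene"), Edge("L", "G", "lncRNA-gene"),
                   Edge("M", "G", "miRNA-gene")],
            status="candidate",
        )
        data = make_dataset(
            {"T": [1, 2, 3, 4], "L": [2, 2, 3, 3], "M": [1, 1, 2, 2],
             "G": [5, 6, 7, 8]},
            roles,
        )
        prob = build_problem("G", net, data)
        assert prob.regressor_matrix.shape == (4, 4)
        assert [et for _, et in prob.regressor_ids] == [
            "TF-gene", "lncRNA-gene", "miRNA-gene"
        ]
        assert prob.constraint_mask.tolist() == [False, False, True, False]
        # miRNA column is response * regulator
        np.testing.assert_allclose(
            prob.regressor_matrix[:, 2],
            np.array([5, 6, 7, 8]) * np.array([1, 1, 2, 2]),
        )

    def test_protein_product_columns(self):
        roles = {"P": "protein", "Q1": "protein", "Q2": "protein"}
        nodes = {k: Node(k, v) for k, v in roles.items()}
        net = GWGEN(
            nodes=nodes,
            edges=[Edge("Q1", "P", "PPI"), Edge("Q2", "P", "PPI")],
            status="candidate",
        )
        data = make_dataset({"P": [1, 2], "Q1": [3, 4], "Q2": [5, 6]}, roles)
        prob = build_problem("P", net, data)
        np.testing.assert_allclose(
            prob.regressor_matrix,
            [[1 * 3, 1 * 5, 1], [2 * 4, 2 * 6, 1]],
        )

    def test_matches_naive_assembly_on_fixture_node(
        self, truth_noisefree, data_noisefree
    ):
        cand = as_candidate(truth_noisefree.network)
        nid = next(
            n for n in sorted(cand.nodes)
            if cand.nodes[n].role == "gene" and len(cand.regulators_of(n)) >= 2
        )
        prob = build_problem(nid, cand, data_noisefree)
        y = data_noisefree.series(nid)
        cols = []
        for reg, etype in prob.regressor_ids:
            x = data_noisefree.series(reg)
            cols.append(y * x if etype.startswith("miRNA") else x)
        cols.append(np.ones_like(y))
        np.testing.assert_allclose(prob.regressor_matrix,
                                   np.column_stack(cols))

    def test_missing_regulator_is_named(self, tiny_candidate):
        data = make_dataset({"A": [1, 2], "B": [1, 2]},
                            {"A": "TF", "B": "gene"})
        with pytest.raises(KeyError, match="C"):
            build_problem("B", tiny_candidate, data)

    def test_zero_regulators_gives_basal_only_problem(self, tiny_candidate):
        data = make_dataset(
            {"A": [1.0, 2.0, 3.0], "B": [1, 1, 1], "C": [1, 1, 1]},
            {"A": "TF", "B": "gene", "C": "miRNA"},
        )
        prob = build_problem("A", tiny_candidate, data)
        assert prob.order == 0
        fit = fit_constrained(prob)
        assert fit.basal == pytest.approx(2.0)

    def test_overparameterized_problem_pre_truncated(self):
        rng = np.random.default_rng(0)
        n, h = 8, 12  # order > N - 2
        roles = {f"T{i}": "TF" for i in range(h)} | {"G": "gene"}
        nodes = {k: Node(k, v) for k, v in roles.items()}
        net = GWGEN(
            nodes=nodes,
            edges=[Edge(f"T{i}", "G", "TF-gene") for i in range(h)],
            status="candidate",
        )
        rows = {f"T{i}": rng.uniform(1, 3, n) for i in range(h)}
        rows["G"] = 2 * rows["T0"] + rng.normal(0, 0.01, n)
        full = build_problem("G", net, make_dataset(rows, roles))
        assert full.order == h  # assembly keeps the full candidate structure
        from gwgen.identify import truncate_problem

        prob = truncate_problem(full)
        assert prob.order == n - 2
        assert prob.truncated_from == h
        assert ("T0", "TF-gene") in prob.regressor_ids
        # the search path truncates transparently
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = g.detect_order(full, "greedy")
        assert res.final_fit.order <= n - 2


class TestFitConstrained:
    def test_exact_line_fit(self):
        prob = RegressionProblem(
            node_id="n", node_class="gene",
            regressor_ids=[("x", "TF-gene")],
            regulator_values=np.array([[1.0], [2.0], [3.0]]),
            response=np.array([2.0, 4.0, 6.0]),
            product_mask=np.array([False]),
            constraint_mask=np.array([False, False]),
        )
        fit = fit_constrained(prob)
        assert fit.estimates[("x", "TF-gene")] == pytest.approx(2.0)
        assert fit.basal == pytest.approx(0.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_constraint_clamps_positive_optimum_to_boundary(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 3, 50)
        y = 0.8 * x + 2.0 + rng.normal(0, 0.05, 50)
        prob = RegressionProblem(
            node_id="n", node_class="gene",
            regressor_ids=[("m", "miRNA-gene")],
            regulator_values=x[:, None],
            response=y,
            product_mask=np.array([False]),  # plain column to force + optimum
            constraint_mask=np.array([True, False]),
        )
        fit = fit_constrained(prob)
        assert fit.estimates[("m", "miRNA-gene")] == 0.0
        assert fit.fitted_under_constraint
        basal_only = float(np.sum((y - y.mean()) ** 2))
        assert fit.rss == pytest.approx(basal_only, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_active_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        phi_reg = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        mask = np.array([True, True, False, False, False])
        prob = RegressionProblem(
            node_id="n", node_class="gene",
            regressor_ids=[(f"r{i}", "miRNA-gene" if mask[i] else "TF-gene")
                           for i in range(4)],
            regulator_values=phi_reg,
            response=y,
            product_mask=np.zeros(4, dtype=bool),
            constraint_mask=mask,
        )
        fit = fit_constrained(prob)
        _, best_obj = active_set_lsq(prob.regressor_matrix, y, mask)
        assert fit.rss == pytest.approx(best_obj, rel=1e-8, abs=1e-10)
        for i, rid in enumerate(prob.regressor_ids):
            if mask[i]:
                assert fit.estimates[rid] <= 1e-12

    def test_unconstrained_residual_orthogonality(self, truth_noisy, data_noisy):
        cand = as_candidate(truth_noisy.network)
        checked = 0
        for nid in sorted(cand.nodes):
            prob = build_problem(nid, cand, data_noisy)
            if prob.order == 0 or prob.constraint_mask.any():
                continue
            fit = fit_constrained(prob)
            phi = prob.regressor_matrix
            resid = prob.response - phi @ fit.coefficients
            assert np.linalg.norm(phi.T @ resid) <= 1e-8 * np.linalg.norm(
                phi.T @ prob.response
            )
            checked += 1
        assert checked >= 5

    def test_rank_deficiency_warns_and_returns_min_norm(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # collinear
        prob = RegressionProblem(
            node_id="n", node_class="gene",
            regressor_ids=[("a", "TF-gene"), ("b", "TF-gene")],
            regulator_values=x,
            response=np.array([1.0, 2.0, 3.0]),
            product_mask=np.zeros(2, dtype=bool),
            constraint_mask=np.zeros(3, dtype=bool),
        )
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_constrained(prob)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_feasibility_property_random_constrained_problems(self):
        """Every fit satisfies its sign constraints exactly (hypothesis)."""
        from hypothesis import given, settings, strategies as st

        @given(st.integers(0, 2**31 - 1))
        @settings(max_examples=30, deadline=None)
        def check(seed):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 40))
            h = int(rng.integers(1, 6))
            mask = np.append(rng.random(h) < 0.5, False)
            prob = RegressionProblem(
                node_id="n", node_class="gene",
                regressor_ids=[
                    (f"r{i}", "miRNA-gene" if mask[i] else "TF-gene")
                    for i in range(h)
                ],
                regulator_values=rng.uniform(1, 3, size=(n, h)),
                response=rng.normal(2.0, 1.0, n),
                product_mask=np.zeros(h, dtype=bool),
                constraint_mask=mask,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_constrained(prob)
            for i, rid in enumerate(prob.regressor_ids):
                if mask[i]:
                    assert fit.estimates[rid] <= 1e-12

        check()

    def test_with_response_rebuilds_product_columns(self):
        x = np.array([[2.0], [3.0], [4.0]])
        prob = RegressionProblem(
            node_id="n", node_class="gene",
            regressor_ids=[("m", "miRNA-gene")],
            regulator_values=x,
            response=np.array([1.0, 1.0, 1.0]),
            product_mask=np.array([True]),
            constraint_mask=np.array([True, False]),
        )
        new = prob.with_response(np.array([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(new.regressor_matrix[:, 0],
                                   [4.0, 6.0, 8.0])
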