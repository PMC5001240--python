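"""Unit and property tests for correlations, influence and orientation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbdn import (
    correlation_matrix,
    influence,
    influence_d,
    influence_matrix,
    orient,
    partial_correlation,
)
from cbdn.influence import (
    DegenerateConditioningError,
    influence_matrix_from_correlation,
)


def _residual_pc(x, y, z):
    """Partial correlation oracle: correlate residuals of x|z and y|z."""
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


class TestCorrelationMatrix:
    def test_matches_sum_of_products_oracle(self, rng):
        data = rng.standard_normal((5, 3))
        expr = pd.DataFrame(data, columns=["A", "B", "C"])
        corr = correlation_matrix(expr)
        for a in range(3):
            for b in range(3):
                x, y = data[:, a], data[:, b]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
                assert corr.iloc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_and_negated_columns(self, rng):
        x = rng.standard_normal(20)
        expr = pd.DataFrame({"A": x, "B": x.copy(), "C": -x})
        corr = correlation_matrix(expr)
        assert corr.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)
        assert corr.loc["A", "C"] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(corr.values, corr.values.T)
        assert np.all(np.diag(corr.values) == 1.0)

    def test_zero_variance_column_rejected(self, rng):
        expr = pd.DataFrame(
            {"A": rng.standard_normal(10), "B": np.full(10, 2.0)}
        )
        with pytest.raises(ValueError, match="B"):
            correlation_matrix(expr)


class TestPartialCorrelation:
    def test_reduces_to_correlation_when_conditioner_uncorrelated(self):
        corr = pd.DataFrame(
            [[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        assert partial_correlation("A", "B", "C", corr) == pytest.approx(0.5)

    def test_markov_chain_conditional_independence(self):
        rho = 0.7
        corr = pd.DataFrame(
            [[1.0, rho, rho**2], [rho, 1.0, rho], [rho**2, rho, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        assert partial_correlation("A", "C", "B", corr) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_in_endpoints_and_matches_residual_oracle(self, rng):
        for _ in range(200):
            data = rng.standard_normal((25, 3)) @ rng.standard_normal((3, 3))
            expr = pd.DataFrame(data, columns=["A", "B", "C"])
            corr = correlation_matrix(expr)
            pc = partial_correlation("A", "B", "C", corr)
            assert pc == partial_correlation("B", "A", "C", corr)
            oracle = _residual_pc(data[:, 0], data[:, 1], data[:, 2])
            assert pc == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_conditioning_raises(self, rng):
        x = rng.standard_normal(15)
        expr = pd.DataFrame({"A": x, "B": 2 * x + 1, "C": rng.standard_normal(15)})
        corr = correlation_matrix(expr)
        with pytest.raises(DegenerateConditioningError):
            partial_correlation("A", "C", "B", corr)


class TestInfluenceScalar:
    def test_zero_when_conditioner_uncorrelated_with_both(self):
        corr = pd.DataFrame(
            [[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        assert influence_d("A", "B", "C", corr) == pytest.approx(0.0, abs=1e-14)

    def test_self_pair_is_zero(self, small_expr):
        corr = correlation_matrix(small_expr)
        assert influence_d("G1", "G1", "G3", corr) == 0.0

    def test_matches_direct_formula(self, small_expr):
        corr = correlation_matrix(small_expr)
        expected = corr.loc["G1", "G2"] - partial_correlation("G1", "G2", "G4", corr)
        assert influence_d("G1", "G2", "G4", corr) == pytest.approx(expected)

    def test_all_independent_population_gives_zero_influence(self):
        corr = pd.DataFrame(np.eye(5), index=list("ABCDE"), columns=list("ABCDE"))
        for j in "ABCDE":
            for i in "ABCDE":
                if i != j:
                    assert influence(j, i, corr) == pytest.approx(0.0, abs=1e-14)

    def test_requires_three_genes(self):
        corr = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            influence("A", "B", corr)


class TestBenchmarkTreeInfluence:
    """Population-level checks on the 10-node benchmark tree.

    Conditioning on the root's child X4 leaves exactly one conditionally
    independent pair (X1, X10), whose correlation change equals
    |Corr(X1, X10)|; the remaining pairs change only at second order, so the
    root's influence on X4 dominates and the edge orients X1 -> X4.
    """

    def test_exact_conditional_independence_term(self, ten_pop_corr):
        d = influence_d("X1", "X10", "X4", ten_pop_corr)
        assert d == pytest.approx(ten_pop_corr.loc["X1", "X10"], abs=1e-12)

    def test_single_pair_term_lower_bounds_child_influence(self, ten_pop_corr):
        lower = abs(ten_pop_corr.loc["X1", "X10"]) / 9
        assert influence("X4", "X1", ten_pop_corr) >= lower

    def test_subtree_terms_lower_bound_root_influence(self, ten_pop_corr):
        # conditioning on the root separates X4 from the other subtrees exactly
        outside = ["X2", "X3", "X5", "X6", "X7", "X8", "X9"]
        for t in outside:
            d = influence_d("X4", t, "X1", ten_pop_corr)
            assert d == pytest.approx(ten_pop_corr.loc["X4", t], abs=1e-12)
        lower = sum(abs(ten_pop_corr.loc["X4", t]) for t in outside) / 9
        assert influence("X1", "X4", ten_pop_corr) >= lower

    def test_root_out_influences_child(self, ten_pop_corr):
        assert influence("X1", "X4", ten_pop_corr) > influence("X4", "X1", ten_pop_corr)


class TestInfluenceMatrix:
    def test_matches_scalar_triple_loop_oracle(self, small_expr):
        corr = correlation_matrix(small_expr)
        D = influence_matrix(small_expr)
        for j in small_expr.columns:
            for i in small_expr.columns:
                expected = 0.0 if i == j else influence(j, i, corr)
                assert D.loc[j, i] == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_zero_diagonal(self, small_expr):
        D = influence_matrix(small_expr)
        assert (D.values >= 0).all()
        assert np.all(np.diag(D.values) == 0.0)

    def test_permuting_genes_permutes_influence(self, small_expr):
        D = influence_matrix(small_expr)
        perm = ["G4", "G1", "G6", "G2", "G5", "G3"]
        D_perm = influence_matrix(small_expr[perm])
        pd.testing.assert_frame_equal(D.loc[perm, perm], D_perm, atol=1e-14, rtol=0)

    def test_invariant_to_shift_and_positive_scaling(self, small_expr):
        D = influence_matrix(small_expr)
        transformed = small_expr * [2.0, 0.5, 3.0, 1.0, 10.0, 0.1] + [5, -3, 0, 1, 2, 7]
        D2 = influence_matrix(transformed)
        assert np.allclose(D.values, D2.values, atol=1e-10)

    def test_rejects_fewer_than_three_genes(self, rng):
        expr = pd.DataFrame(rng.standard_normal((10, 2)), columns=["A", "B"])
        with pytest.raises(ValueError):
            influence_matrix(expr)


class TestOrient:
    def test_benchmark_edge_direction(self, ten_pop_influence):
        pairs = orient(ten_pop_influence)
        assert ("X1", "X4") in {(s, t) for s, t, _ in pairs.edges}

    def test_exact_tie_recorded_not_oriented(self):
        D = pd.DataFrame(
            [[0.0, 0.5, 0.1], [0.5, 0.0, 0.3], [0.2, 0.3, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        pairs = orient(D)
        assert ("A", "B") in pairs.ties
        assert ("B", "C") in pairs.ties
        edge_pairs = {frozenset((s, t)) for s, t, _ in pairs.edges}
        assert frozenset(("A", "B")) not in edge_pairs
        assert edge_pairs == {frozenset(("A", "C"))}  # C -> A remains

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=20, max_size=20
        )
    )
    def test_partition_property_for_arbitrary_influence_values(self, flat):
        """edges and ties partition the unordered pairs for any influence matrix."""
        genes = list("ABCDE")
        D = pd.DataFrame(np.zeros((5, 5)), index=genes, columns=genes)
        D.values[~np.eye(5, dtype=bool)] = flat
        pairs = orient(D)
        covered = [frozenset((s, t)) for s, t, _ in pairs.edges]
        covered += [frozenset(p) for p in pairs.ties]
        assert sorted(covered, key=sorted) == sorted(
            (frozenset((a, b)) for i, a in enumerate(genes) for b in genes[i + 1 :]),
            key=sorted,
        )
        for s, t, w in pairs.edges:
            assert w == D.loc[s, t] > D.loc[t, s]

    def test_every_unordered_pair_covered_exactly_once(self, rng):
        n = 7
        genes = [f"G{i}" for i in range(n)]
        D = pd.DataFrame(rng.random((n, n)), index=genes, columns=genes)
        np.fill_diagonal(D.values, 0.0)
        pairs = orient(D)
        covered = [frozenset((s, t)) for s, t, _ in pairs.edges]
        covered += [frozenset(p) for p in pairs.ties]
        assert len(covered) == len(set(covered)) == n * (n - 1) // 2
        # no two-gene cycles, weights are the winning influences
        for s, t, w in pairs.edges:
            assert D.loc[s, t] == w > D.loc[t, s]
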