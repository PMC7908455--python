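"""Unit and property tests for the AHP core: parsing, validation, weights,
lambda_max estimation, consistency, and judgment aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swotahp import (
    ComparisonMatrix,
    JudgmentError,
    MatrixValidationError,
    UnsupportedOrderError,
    aggregate_judgments,
    consistency_check,
    estimate_lambda_max,
    geometric_mean_weights,
    parse_judgment,
    validate_comparison_matrix,
)
from swotahp.simulate import make_consistent_matrix

from conftest import principal_eigen_weights, principal_eigenvalue


# ---------------------------------------------------------------- judgments
@pytest.mark.parametrize(
    "text, expected",
    [("1/3", 1 / 3), ("5", 5.0), (3, 3.0), ("2.5", 2.5), ("9", 9.0), ("1/9", 1 / 9)],
)
def test_parse_judgment_values(text, expected):
    assert parse_judgment(text) == pytest.approx(expected, rel=1e-15)


@pytest.mark.parametrize("text", ["0", "-2", "1/0", "abc", "", "3/0"])
def test_parse_judgment_rejects_bad_input(text):
    with pytest.raises(JudgmentError):
        parse_judgment(text)


# --------------------------------------------------------------- validation
def test_validate_accepts_case_matrix(case_matrices):
    m = case_matrices["W"]
    assert m.n == 3
    assert m.labels == ("W1", "W2", "W3")
    assert np.allclose(np.diag(m.values), 1.0)


def test_validate_all_equal_judgments():
    m = validate_comparison_matrix(np.ones((3, 3)))
    assert m.n == 3


def test_validate_reports_reciprocity_violation():
    with pytest.raises(MatrixValidationError, match=r"\(0, 1\)"):
        validate_comparison_matrix([[1, 2], [3, 1]])


@pytest.mark.parametrize(
    "entries",
    [
        [[1, 2, 3], [0.5, 1, 4]],  # non-square
        [[1]],  # order < 2
        [[1, -2], [-0.5, 1]],  # non-positive
    ],
)
def test_validate_rejects_malformed(entries):
    with pytest.raises(MatrixValidationError):
        validate_comparison_matrix(entries)


def test_validate_fills_missing_reciprocals():
    m = validate_comparison_matrix([[1, 3], [None, 1]])
    assert m.values[1, 0] == pytest.approx(1 / 3)


def test_off_scale_entries_warn_by_default_and_fail_strict():
    rows = [[1, 3.5], [1 / 3.5, 1]]
    with pytest.warns(UserWarning, match="off the fundamental"):
        validate_comparison_matrix(rows)
    with pytest.raises(MatrixValidationError):
        validate_comparison_matrix(rows, strict_saaty=True)


# ------------------------------------------------------------------ weights
def test_case_weaknesses_weights_match_published(case_matrices):
    w = geometric_mean_weights(case_matrices["W"]).weights
    assert np.round(w, 4) == pytest.approx([0.2184, 0.1515, 0.6301], abs=1e-12)


def test_all_ones_matrix_gives_uniform_weights():
    m = validate_comparison_matrix(np.ones((5, 5)))
    assert geometric_mean_weights(m).weights == pytest.approx(np.full(5, 0.2))


def test_consistent_matrix_recovers_defining_weights():
    w_true = np.array([0.5, 0.3, 0.2])
    m = make_consistent_matrix(w_true)
    assert geometric_mean_weights(m).weights == pytest.approx(w_true, abs=1e-14)


def test_weights_normalized_and_positive(case_matrices):
    for m in case_matrices.values():
        w = geometric_mean_weights(m).weights
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w > 0)


def test_n3_geometric_mean_equals_eigenvector_oracle(case_matrices):
    """For order 3 the row-geometric-mean weights equal the principal
    eigenvector weights; check against numpy's eigen-solver."""
    for key in ("W", "O", "T"):
        m = case_matrices[key]
        gm = geometric_mean_weights(m).weights
        ev = principal_eigen_weights(m.values)
        assert gm == pytest.approx(ev, abs=1e-6)


# --------------------------------------------------------------- lambda_max
def test_case_lambda_max_values(case_matrices):
    expected = {"S": 4.0484, "W": 3.1078, "O": 3.0536, "T": 3.0183}
    for key, m in case_matrices.items():
        lam = estimate_lambda_max(m, geometric_mean_weights(m))
        assert round(lam, 4) == pytest.approx(expected[key], abs=1e-12)


def test_lambda_max_is_n_for_consistent_matrix():
    m = make_consistent_matrix([0.6, 0.25, 0.1, 0.05])
    lam = estimate_lambda_max(m, geometric_mean_weights(m))
    assert lam == pytest.approx(4.0, abs=1e-10)


def test_lambda_max_close_to_eigen_oracle(case_matrices):
    m = case_matrices["S"]
    lam = estimate_lambda_max(m, geometric_mean_weights(m))
    assert abs(lam - principal_eigenvalue(m.values)) < 0.01


@given(
    st.lists(
        st.floats(min_value=-2.1972, max_value=2.1972),  # log(1/9)..log(9)
        min_size=6,
        max_size=6,
    )
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_lambda_max_at_least_n_for_reciprocal_matrices(logs):
    """Eigenvalue-estimate lower bound lambda_max >= n for any positive
    reciprocal matrix (follows from x + 1/x >= 2 applied pairwise)."""
    A = np.ones((4, 4))
    iu = np.triu_indices(4, k=1)
    A[iu] = np.exp(logs)
    A[(iu[1], iu[0])] = 1.0 / A[iu]
    m = ComparisonMatrix(values=A, labels=("a", "b", "c", "d"))
    lam = estimate_lambda_max(m, geometric_mean_weights(m))
    assert lam >= 4 - 1e-9


# -------------------------------------------------------------- consistency
def test_case_consistency_values(case_matrices):
    rep = consistency_check(case_matrices["W"])
    assert rep.ci == pytest.approx(0.0539, abs=5e-5)
    assert rep.cr == pytest.approx(0.0929, abs=2e-4)
    assert rep.passes
    rep_o = consistency_check(case_matrices["O"])
    assert round(rep_o.cr, 4) == pytest.approx(0.0462, abs=1e-12)


def test_consistent_matrix_has_zero_ci_cr():
    rep = consistency_check(make_consistent_matrix([0.5, 0.3, 0.2]))
    assert rep.ci == pytest.approx(0.0, abs=1e-12)
    assert rep.cr == pytest.approx(0.0, abs=1e-12)
    assert rep.passes


def test_order_two_defined_consistent():
    rep = consistency_check(validate_comparison_matrix([[1, 7], ["1/7", 1]]))
    assert rep.cr == 0.0 and rep.passes


def test_order_beyond_ri_table_errors_unless_extended():
    n = 11
    m = make_consistent_matrix(np.full(n, 1.0 / n))
    with pytest.raises(UnsupportedOrderError):
        consistency_check(m)
    rep = consistency_check(m, ri_table={11: 1.51})
    assert rep.passes


def test_permutation_invariance(case_matrices):
    """Permuting factors permutes weights identically and leaves the
    consistency diagnostics unchanged."""
    m = case_matrices["S"]
    perm = [2, 0, 3, 1]
    A = m.values[np.ix_(perm, perm)]
    mp = ComparisonMatrix(values=A, labels=tuple(m.labels[i] for i in perm))
    w, wp = geometric_mean_weights(m).weights, geometric_mean_weights(mp).weights
    assert wp == pytest.approx(w[perm], abs=1e-12)
    r, rp = consistency_check(m), consistency_check(mp)
    assert rp.lambda_max == pytest.approx(r.lambda_max, abs=1e-10)
    assert rp.cr == pytest.approx(r.cr, abs=1e-10)


# -------------------------------------------------------------- aggregation
def test_aggregate_is_idempotent_on_copies(case_matrices):
    m = case_matrices["T"]
    agg = aggregate_judgments([m, m, m])
    assert agg.values == pytest.approx(m.values, abs=1e-12)


def test_aggregate_geometric_mean_of_two_judgments():
    m1 = validate_comparison_matrix([[1, 2], ["1/2", 1]])
    m2 = validate_comparison_matrix([[1, 8], ["1/8", 1]])
    assert aggregate_judgments([m1, m2]).values[0, 1] == pytest.approx(4.0)


def test_aggregate_reciprocal_pair_cancels():
    m1 = validate_comparison_matrix([[1, 3], ["1/3", 1]])
    m2 = validate_comparison_matrix([[1, "1/3"], [3, 1]])
    assert aggregate_judgments([m1, m2]).values[0, 1] == pytest.approx(1.0)


def test_aggregate_rejects_mismatched_labels(case_matrices):
    with pytest.raises(MatrixValidationError):
        aggregate_judgments([case_matrices["W"], case_matrices["O"]])


@given(
    st.lists(
        st.lists(st.floats(min_value=-2.0, max_value=2.0), min_size=3, max_size=3),
        min_size=1,
        max_size=4,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_aggregate_preserves_reciprocity(panel_logs):
    """Element-wise geometric-mean aggregation keeps a_ij * a_ji = 1."""
    mats = []
    for logs in panel_logs:
        A = np.ones((3, 3))
        iu = np.triu_indices(3, k=1)
        A[iu] = np.exp(logs)
        A[(iu[1], iu[0])] = 1.0 / A[iu]
        mats.append(ComparisonMatrix(values=A, labels=("a", "b", "c")))
    agg = aggregate_judgments(mats)
    assert agg.values * agg.values.T == pytest.approx(np.ones((3, 3)), abs=1e-9)
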