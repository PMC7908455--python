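"""Analytic Hierarchy Process core: comparison matrices, priority weights,
and the consistency check.

A pairwise comparison matrix ``A = (a_ij)`` is positive and reciprocal
(``a_ij * a_ji = 1``), with ``a_ij`` the judged importance of factor *i* over
factor *j* on the Saaty 1-9 scale.  Priority weights are estimated by the
product-square-root (row geometric mean) method:

    gm_i = (prod_j a_ij) ** (1/n),      w_i = gm_i / sum_k gm_k

The principal eigenvalue is estimated from those weights as

    lambda_max = (1/n) * sum_i (A w)_i / w_i

which is exact for a consistent matrix (lambda_max = n) and, for reciprocal
matrices, never below n.  The consistency index CI = (lambda_max - n)/(n - 1)
is normalized by the expected CI of random reciprocal matrices of the same
order (the random index RI); the judgment set is conventionally acceptable
when CR = CI/RI < 0.1.

For n = 3 the geometric-mean weights coincide with the principal-eigenvector
weights; for larger n they are a close, widely used approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    JudgmentError,
    MatrixValidationError,
    UnsupportedOrderError,
)

__all__ = [
    "SAATY_SCALE",
    "RANDOM_INDEX",
    "CR_THRESHOLD",
    "parse_judgment",
    "is_saaty_value",
    "ComparisonMatrix",
    "validate_comparison_matrix",
    "WeightVector",
    "geometric_mean_weights",
    "estimate_lambda_max",
    "ConsistencyReport",
    "consistency_check",
    "aggregate_judgments",
]

#: The fundamental scale of absolute numbers: 1..9 and their reciprocals.
SAATY_SCALE: tuple[float, ...] = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(
    float(k) for k in range(1, 10)
)

#: Average random consistency index by matrix order (expected CI of random
#: reciprocal matrices); orders 1 and 2 are structurally consistent.
RANDOM_INDEX: Mapping[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

#: Conventional acceptability threshold on the consistency ratio.
CR_THRESHOLD: float = 0.1


def parse_judgment(text: str | float | int) -> float:
    """Parse a single pairwise judgment such as ``"3"``, ``"1/3"`` or ``2.5``.

    Fraction strings are evaluated exactly; plain numbers pass through.
    Raises :class:`JudgmentError` for zero, negative, or unparseable input.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        value = float(text)
    else:
        s = str(text).strip()
        try:
            value = float(Fraction(s))
        except ZeroDivisionError:
            raise JudgmentError(f"judgment {text!r} has a zero denominator") from None
        except ValueError:
            try:
                value = float(s)
            except ValueError:
                raise JudgmentError(f"cannot parse judgment {text!r}") from None
    if not math.isfinite(value) or value <= 0:
        raise JudgmentError(f"judgment {text!r} is not strictly positive")
    return value


def is_saaty_value(value: float, tol: float = 1e-6) -> bool:
    """True if ``value`` lies on the fundamental scale within relative ``tol``."""
    return any(abs(value - s) <= tol * s for s in SAATY_SCALE)


@dataclass(frozen=True)
class ComparisonMatrix:
    """A validated positive reciprocal pairwise-comparison matrix.

    Construct through :func:`validate_comparison_matrix`; instances are
    immutable and carry factor labels aligned with the row/column order.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        self.values.flags.writeable = False


def _parse_entries(entries: Sequence[Sequence[object]]) -> np.ndarray:
    rows = list(entries)
    out = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=float)
    for i, row in enumerate(rows):
        cells = list(row)
        if len(cells) != out.shape[1]:
            raise MatrixValidationError(
                f"row {i} has {len(cells)} entries, expected {out.shape[1]}"
            )
        for j, cell in enumerate(cells):
            if cell is None:
                out[i, j] = np.nan  # fill from the transpose below
                continue
            try:
                out[i, j] = parse_judgment(cell)
            except JudgmentError as exc:
                raise MatrixValidationError(f"cell ({i}, {j}): {exc}") from exc
    return out


def validate_comparison_matrix(
    entries: Sequence[Sequence[object]] | np.ndarray,
    labels: Sequence[str] | None = None,
    tol: float = 1e-6,
    strict_saaty: bool = False,
) -> ComparisonMatrix:
    """Validate (and complete) a pairwise-comparison matrix.

    Cells may be numbers or fraction strings (``"1/3"``); ``None`` cells are
    filled as the reciprocal of the mirror entry.  The diagonal is forced to
    exactly 1.  Reciprocity ``a_ij * a_ji = 1`` is enforced within relative
    ``tol``.  Off-scale entries (not on the Saaty set) warn by default and
    raise under ``strict_saaty``.
    """
    A = _parse_entries(entries) if not isinstance(entries, np.ndarray) else entries.astype(float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MatrixValidationError(f"matrix must be square, got shape {A.shape}")
    n = A.shape[0]
    if n < 2:
        raise MatrixValidationError(f"matrix order must be >= 2, got {n}")

    # fill missing cells from the transpose before any checks
    missing = np.isnan(A)
    if missing.any():
        if (missing & missing.T).any() or missing.diagonal().any():
            raise MatrixValidationError("a judgment and its reciprocal are both missing")
        A[missing] = 1.0 / A.T[missing]

    if not np.all(np.isfinite(A)) or np.any(A <= 0):
        bad = np.argwhere(~np.isfinite(A) | (A <= 0))[0]
        raise MatrixValidationError(
            f"entry ({bad[0]}, {bad[1]}) is not strictly positive and finite"
        )

    prod = A * A.T
    off = np.abs(prod - 1.0) > tol
    np.fill_diagonal(off, False)
    if off.any():
        i, j = np.argwhere(off)[0]
        raise MatrixValidationError(
            f"reciprocity violated at ({i}, {j}): "
            f"a_ij * a_ji = {prod[i, j]:.6g}, expected 1 within tol={tol:g}"
        )
    np.fill_diagonal(A, 1.0)

    offscale = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if not is_saaty_value(A[i, j])
    ]
    if offscale:
        msg = (
            f"{len(offscale)} judgment(s) off the fundamental 1-9 scale, "
            f"first at {offscale[0]}"
        )
        if strict_saaty:
            raise MatrixValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    if labels is None:
        labels = tuple(f"F{i + 1}" for i in range(n))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise MatrixValidationError(
                f"{len(labels)} labels for a matrix of order {n}"
            )
    return ComparisonMatrix(values=A, labels=labels)


@dataclass(frozen=True)
class WeightVector:
    """Row geometric means and the normalized priority weights."""

    geometric_means: np.ndarray
    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.geometric_means.flags.writeable = False
        self.weights.flags.writeable = False


def geometric_mean_weights(matrix: ComparisonMatrix) -> WeightVector:
    """Priority weights by the product-square-root (row geometric mean) method."""
    A = matrix.values
    n = matrix.n
    # geometric mean in log space for numerical safety at larger n
    gm = np.exp(np.log(A).sum(axis=1) / n)
    w = gm / gm.sum()
    return WeightVector(geometric_means=gm, weights=w, labels=matrix.labels)


def estimate_lambda_max(matrix: ComparisonMatrix, weights: WeightVector) -> float:
    """Estimate the principal eigenvalue as mean_i (A w)_i / (n w_i).

    Exact when the matrix is consistent; for any positive reciprocal matrix
    the estimate is >= n.
    """
    w = weights.weights
    if np.any(w <= 0):
        raise MatrixValidationError("weights must be strictly positive")
    return float(np.mean(matrix.values @ w / w))


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one comparison matrix."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passes: bool


def consistency_check(
    matrix: ComparisonMatrix,
    weights: WeightVector | None = None,
    ri_table: Mapping[int, float] | None = None,
) -> ConsistencyReport:
    """Compute lambda_max, CI = (lambda_max - n)/(n - 1), and CR = CI/RI.

    Orders 1 and 2 are structurally consistent: CR is defined as 0 and passes.
    Orders beyond the random-index table raise :class:`UnsupportedOrderError`
    unless ``ri_table`` supplies an extension.
    """
    table = dict(RANDOM_INDEX)
    if ri_table:
        table.update(ri_table)
    n = matrix.n
    if n not in table:
        raise UnsupportedOrderError(
            f"no random index for order {n}; supply ri_table to extend"
        )
    if weights is None:
        weights = geometric_mean_weights(matrix)
    lam = estimate_lambda_max(matrix, weights)
    ri = table[n]
    if n <= 2:
        ci, cr = 0.0, 0.0
    else:
        ci = (lam - n) / (n - 1)
        cr = ci / ri
    return ConsistencyReport(
        n=n, lambda_max=lam, ci=ci, ri=ri, cr=cr, passes=cr < CR_THRESHOLD
    )


def aggregate_judgments(matrices: Iterable[ComparisonMatrix]) -> ComparisonMatrix:
    """Aggregate expert matrices by the element-wise geometric mean (AIJ).

    The geometric mean is the standard aggregation that preserves reciprocity;
    the result is re-symmetrized exactly (lower triangle set to reciprocals).
    """
    ms = list(matrices)
    if not ms:
        raise MatrixValidationError("need at least one matrix to aggregate")
    labels = ms[0].labels
    n = ms[0].n
    for k, m in enumerate(ms[1:], start=1):
        if m.n != n or m.labels != labels:
            raise MatrixValidationError(
                f"matrix {k} has order/labels differing from matrix 0"
            )
    logs = np.mean([np.log(m.values) for m in ms], axis=0)
    A = np.exp(logs)
    iu = np.triu_indices(n, k=1)
    A[(iu[1], iu[0])] = 1.0 / A[iu]
    np.fill_diagonal(A, 1.0)
    return ComparisonMatrix(values=A, labels=labels)
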