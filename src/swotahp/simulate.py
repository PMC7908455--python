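"""Synthetic expert-judgment generation.

Emulates an expert panel answering a pairwise-comparison questionnaire.  A
true weight vector defines the consistent matrix a_ij = w_i / w_j; each
simulated expert perturbs every upper-triangle judgment multiplicatively with
log-normal noise, a_ij * exp(eps), eps ~ N(0, sigma^2) — the standard
sign-safe error model for reciprocal matrices — and may quantize judgments to
the nearest Saaty value in log space (ties broken toward 1, the "equal
importance" end).  Reciprocity is exact by construction, so every generated
matrix validates; sigma = 0 without quantization reproduces the consistent
matrix and hence CR = 0.

All randomness flows from one master seed through ``numpy``'s SeedSequence
spawning (PCG64), so panels and whole configurations are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ahp import SAATY_SCALE, ComparisonMatrix, validate_comparison_matrix
from .config import AnalysisConfig, AnalysisOptions, FactorSpec, GroupSpec, GROUP_KEYS
from .errors import MatrixValidationError, UnsupportedOrderError
from . import ahp

__all__ = [
    "SyntheticPanelSpec",
    "make_consistent_matrix",
    "snap_to_saaty",
    "perturb_matrix",
    "generate_panel",
    "generate_swot_config",
]

_LOG_SCALE = tuple(math.log(s) for s in SAATY_SCALE)


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of a simulated expert panel for one comparison matrix."""

    true_weights: tuple[float, ...]
    n_experts: int = 1
    sigma: float = 0.0
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if w.ndim != 1 or w.size < 2 or np.any(w <= 0):
            raise MatrixValidationError(
                "true_weights must be >= 2 strictly positive numbers"
            )
        if abs(w.sum() - 1.0) > 1e-9:
            raise MatrixValidationError(
                f"true_weights must sum to 1, got {w.sum()!r}"
            )
        if self.n_experts < 1:
            raise MatrixValidationError("n_experts must be >= 1")
        if self.sigma < 0:
            raise MatrixValidationError("sigma must be non-negative")


def make_consistent_matrix(
    true_weights, labels=None
) -> ComparisonMatrix:
    """Exactly consistent matrix a_ij = w_i / w_j from a weight vector."""
    w = np.asarray(true_weights, dtype=float)
    if np.any(w <= 0):
        raise MatrixValidationError("weights must be strictly positive")
    A = w[:, None] / w[None, :]
    np.fill_diagonal(A, 1.0)
    if labels is None:
        labels = tuple(f"F{i + 1}" for i in range(len(w)))
    return ComparisonMatrix(values=A, labels=tuple(labels))


def snap_to_saaty(value: float) -> float:
    """Nearest Saaty-scale value in log space; ties go toward 1."""
    if value <= 0:
        raise MatrixValidationError(f"judgment must be positive, got {value}")
    lv = math.log(value)
    # distances rounded so float jitter cannot hide an exact tie; ties then
    # resolve to the candidate nearer 1 (smaller |log|)
    best = min(
        zip(_LOG_SCALE, SAATY_SCALE),
        key=lambda p: (round(abs(lv - p[0]), 12), abs(p[0])),
    )
    return best[1]


def perturb_matrix(
    matrix: ComparisonMatrix,
    sigma: float,
    seed: int | np.random.Generator = 0,
    quantize: bool = False,
) -> ComparisonMatrix:
    """One simulated expert's reading of ``matrix``.

    Upper-triangle entries are multiplied by exp(eps), eps ~ N(0, sigma^2)
    i.i.d.; the lower triangle is set to exact reciprocals and the diagonal
    stays 1.  ``quantize`` snaps judgments to the Saaty scale afterwards.
    """
    if sigma < 0:
        raise MatrixValidationError("sigma must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = matrix.values.copy()
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    if sigma > 0:
        A[iu] = A[iu] * np.exp(rng.normal(0.0, sigma, size=len(iu[0])))
    if quantize:
        A[iu] = [snap_to_saaty(x) for x in A[iu]]
    A[(iu[1], iu[0])] = 1.0 / A[iu]
    np.fill_diagonal(A, 1.0)
    return ComparisonMatrix(values=A, labels=matrix.labels)


def generate_panel(spec: SyntheticPanelSpec) -> list[ComparisonMatrix]:
    """Independent perturbed matrices, one per expert, from one master seed."""
    base = make_consistent_matrix(spec.true_weights)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_experts)
    return [
        perturb_matrix(base, spec.sigma, np.random.default_rng(ss), spec.quantize)
        for ss in children
    ]


_GROUP_THEMES = {
    "S": "internal strength",
    "W": "internal weakness",
    "O": "external opportunity",
    "T": "external threat",
}


def generate_swot_config(
    group_sizes=(4, 3, 3, 3),
    seed: int = 0,
    sigma: float = 0.0,
    n_experts: int = 1,
    quantize: bool = False,
    title: str = "Synthetic SWOT-AHP analysis",
) -> AnalysisConfig:
    """A complete random-but-reproducible analysis configuration.

    Per group: true weights drawn from a flat Dirichlet (symmetric positive,
    normalized), a panel of ``n_experts`` perturbed matrices aggregated by
    geometric mean, and integer strengths uniform on 0..5.
    """
    sizes = tuple(int(s) for s in group_sizes)
    if len(sizes) != 4 or any(s < 1 for s in sizes):
        raise MatrixValidationError("group_sizes must be four integers >= 1")
    if any(s > max(ahp.RANDOM_INDEX) for s in sizes):
        raise UnsupportedOrderError(
            f"group sizes above {max(ahp.RANDOM_INDEX)} exceed the random-index table"
        )
    master = np.random.SeedSequence(seed)
    group_seqs = master.spawn(4)
    groups: dict[str, GroupSpec] = {}
    for key, size, seq in zip(GROUP_KEYS, sizes, group_seqs):
        rng = np.random.default_rng(seq)
        ids = [f"{key}{i + 1}" for i in range(size)]
        if size == 1:
            matrix = None
        else:
            true_w = rng.dirichlet(np.ones(size))
            base = make_consistent_matrix(true_w, labels=ids)
            panel = [
                perturb_matrix(base, sigma, np.random.default_rng(ss), quantize)
                for ss in seq.spawn(n_experts)
            ]
            matrix = ahp.aggregate_judgments(panel)
        strengths = rng.integers(0, 6, size=size)
        factors = tuple(
            FactorSpec(
                id=i,
                label=f"Synthetic {_GROUP_THEMES[key]} {i}",
                strength=float(st),
                description="synthetic factor generated for testing",
            )
            for i, st in zip(ids, strengths)
        )
        groups[key] = GroupSpec(key=key, factors=factors, matrix=matrix)
    return AnalysisConfig(
        title=title,
        analyst="swotahp.simulate",
        groups=groups,
        options=AnalysisOptions(),
    )
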