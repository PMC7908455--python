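"""End-to-end analysis: weights -> consistency gate -> intensities -> vector.

``run_full_analysis`` executes every stage on a validated configuration and
returns both the full-precision result objects and the fixed-precision
printed summary (see :mod:`swotahp.report`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ahp import (
    ComparisonMatrix,
    ConsistencyReport,
    WeightVector,
    consistency_check,
    geometric_mean_weights,
)
from .config import GROUP_KEYS, AnalysisConfig, AnalysisOptions
from .errors import ConsistencyGateError
from .intensity import SwotGroupResult, group_total
from .report import GroupPrintInputs, printed_summary
from .vector import (
    StrategicQuadrilateral,
    StrategyCall,
    azimuth,
    build_quadrilateral,
    centroid,
    classify_strategy,
    intensity_coefficient,
    strategic_intensities,
)

__all__ = ["GroupAnalysis", "StrategicVectorResult", "AnalysisResult", "run_full_analysis"]


@dataclass(frozen=True)
class GroupAnalysis:
    """Per-group AHP outputs at full precision."""

    key: str
    matrix: ComparisonMatrix | None
    weights: WeightVector
    consistency: ConsistencyReport
    intensities: SwotGroupResult


@dataclass(frozen=True)
class StrategicVectorResult:
    """Full-precision strategic vector."""

    x: float
    y: float
    theta_deg: float
    u: float
    v: float
    rho: float


@dataclass(frozen=True)
class AnalysisResult:
    title: str
    analyst: str
    groups: Mapping[str, GroupAnalysis]
    quadrilateral: StrategicQuadrilateral
    vector: StrategicVectorResult
    call: StrategyCall
    printed: dict
    options: AnalysisOptions = field(default_factory=AnalysisOptions)


def run_full_analysis(config: AnalysisConfig, cr_gate: str | None = None) -> AnalysisResult:
    """Run the complete SWOT-AHP pipeline on a validated configuration.

    Raises :class:`ConsistencyGateError` naming the offending group when any
    consistency ratio is >= 0.1 (demote to a warning with ``cr_gate="warn"``
    or via the config options); degenerate analyses (rho undefined) raise
    :class:`DegenerateAnalysisError`.
    """
    gate = cr_gate if cr_gate is not None else config.options.cr_gate
    if gate not in ("error", "warn"):
        raise ValueError(f"cr_gate must be 'error' or 'warn', got {gate!r}")

    groups: dict[str, GroupAnalysis] = {}
    print_inputs: dict[str, GroupPrintInputs] = {}
    for key in GROUP_KEYS:
        spec = config.groups[key]
        if spec.matrix is None:  # single-factor group: weight 1, trivially consistent
            wv = WeightVector(
                geometric_means=np.array([1.0]),
                weights=np.array([1.0]),
                labels=(spec.factors[0].id,),
            )
            report = ConsistencyReport(
                n=1, lambda_max=1.0, ci=0.0, ri=0.0, cr=0.0, passes=True
            )
        else:
            wv = geometric_mean_weights(spec.matrix)
            report = consistency_check(spec.matrix, wv)
        if not report.passes:
            msg = (
                f"group {key}: CR = {report.cr:.4f} >= 0.1 — pairwise judgments "
                "are too inconsistent to trust the weights"
            )
            if gate == "error":
                raise ConsistencyGateError(msg)
            warnings.warn(msg, stacklevel=2)
        strengths = tuple(f.strength for f in spec.factors)
        intensities = group_total(
            key,
            weights=list(wv.weights),
            strengths=list(strengths),
            ids=[f.id for f in spec.factors],
            labels=[f.label for f in spec.factors],
            weight_tol=1e-9,
        )
        groups[key] = GroupAnalysis(
            key=key, matrix=spec.matrix, weights=wv, consistency=report,
            intensities=intensities,
        )
        print_inputs[key] = GroupPrintInputs(
            key=key,
            ids=tuple(f.id for f in spec.factors),
            labels=tuple(f.label for f in spec.factors),
            geometric_means=wv.geometric_means,
            lambda_max=report.lambda_max,
            ri=report.ri,
            n=report.n,
            strengths=strengths,
        )

    quad = build_quadrilateral(
        groups["S"].intensities.total_intensity,
        groups["W"].intensities.total_intensity,
        groups["O"].intensities.total_intensity,
        groups["T"].intensities.total_intensity,
    )
    x, y = centroid(quad)
    u, v = strategic_intensities(quad)
    rho = intensity_coefficient(u, v)
    vector = StrategicVectorResult(
        x=x, y=y, theta_deg=azimuth(x, y), u=u, v=v, rho=rho
    )
    call = classify_strategy((x, y), rho)
    printed = printed_summary(
        print_inputs,
        ndigits=config.options.rounding,
        theta_digits=config.options.theta_rounding,
    )
    return AnalysisResult(
        title=config.title,
        analyst=config.analyst,
        groups=groups,
        quadrilateral=quad,
        vector=vector,
        call=call,
        printed=printed,
        options=config.options,
    )
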