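"""Signed factor and group intensities.

Each SWOT factor carries an *estimated strength* — a 0-5 rating of its actual
magnitude — and a within-group AHP weight.  Its intensity is the product,
signed by group membership: strengths (S) and opportunities (O) act
positively, weaknesses (W) and threats (T) negatively.  Group totals are the
signed sums; since the weights within a group sum to one, a group total is a
convex combination of strengths and can never exceed 5 in magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .errors import MatrixValidationError, SwotAhpError

__all__ = [
    "GROUP_SIGNS",
    "STRENGTH_MAX",
    "SwotFactor",
    "SwotGroupResult",
    "factor_intensity",
    "group_total",
]

GROUP_SIGNS = {"S": 1, "W": -1, "O": 1, "T": -1}
STRENGTH_MAX = 5.0


class IntensityError(SwotAhpError, ValueError):
    """Invalid weight, strength, or group for an intensity computation."""


def _check_group(group: str) -> str:
    g = str(group).upper()
    if g not in GROUP_SIGNS:
        raise IntensityError(f"group must be one of S, W, O, T, got {group!r}")
    return g


def factor_intensity(weight: float, strength: float, group: str) -> float:
    """Signed intensity = sign(group) * strength * weight.

    ``strength`` is a non-negative magnitude on the 0-5 scale regardless of
    group; the sign comes from group membership alone.
    """
    g = _check_group(group)
    if not 0.0 <= weight <= 1.0:
        raise IntensityError(f"weight {weight} outside [0, 1]")
    if not 0.0 <= strength <= STRENGTH_MAX:
        raise IntensityError(f"strength {strength} outside [0, {STRENGTH_MAX:g}]")
    return GROUP_SIGNS[g] * strength * weight


@dataclass(frozen=True)
class SwotFactor:
    """One weighted, rated SWOT factor with its signed intensity."""

    id: str
    group: str
    label: str
    weight: float
    strength: float
    intensity: float


@dataclass(frozen=True)
class SwotGroupResult:
    """All factors of one group plus the signed total intensity."""

    group: str
    factors: tuple[SwotFactor, ...]
    total_intensity: float


def group_total(
    group: str,
    weights: Sequence[float],
    strengths: Sequence[float],
    ids: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
    weight_tol: float = 1e-9,
) -> SwotGroupResult:
    """Compute per-factor intensities and their signed sum for one group.

    Weights must sum to 1 within ``weight_tol`` (they come from a normalized
    AHP weight vector).  Negative strengths for W/T groups — the common way
    pre-signed tables are written — are normalized to magnitudes with a
    warning; the sign convention is applied from group membership.
    """
    g = _check_group(group)
    if len(weights) == 0:
        raise IntensityError(f"group {g} has no factors")
    if len(weights) != len(strengths):
        raise IntensityError(
            f"group {g}: {len(weights)} weights vs {len(strengths)} strengths"
        )
    total_w = float(sum(weights))
    if abs(total_w - 1.0) > weight_tol:
        raise MatrixValidationError(
            f"group {g}: weights sum to {total_w!r}, expected 1 within {weight_tol:g}"
        )
    strengths = list(strengths)
    if any(s < 0 for s in strengths):
        if GROUP_SIGNS[g] < 0:
            warnings.warn(
                f"group {g}: negative strengths treated as magnitudes "
                "(sign is applied from group membership)",
                stacklevel=2,
            )
            strengths = [abs(s) for s in strengths]
        # positive groups fall through to factor_intensity's range check

    ids = list(ids) if ids is not None else [f"{g}{k + 1}" for k in range(len(weights))]
    labels = list(labels) if labels is not None else ids
    factors = tuple(
        SwotFactor(
            id=i,
            group=g,
            label=lab,
            weight=float(w),
            strength=float(s),
            intensity=factor_intensity(w, s, g),
        )
        for i, lab, w, s in zip(ids, labels, weights, strengths)
    )
    return SwotGroupResult(
        group=g,
        factors=factors,
        total_intensity=float(sum(f.intensity for f in factors)),
    )
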