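"""Strategic quadrilateral and strategic vector (theta, rho).

The four group totals are plotted on four semi-axes — S on +x, W on -x, O on
+y, T on -y — forming the strategic quadrilateral.  Its centroid

    P(X, Y) = ((sum_S + sum_W)/4, (sum_O + sum_T)/4)

points toward the dominant side of the analysis.  The strategic azimuth theta
is the angle of P from the positive x-axis (two-argument arctangent, mapped
to [0, 360) degrees), and determines the strategy quadrant:

    X>0, Y>0 -> SO (growth: strengths x opportunities)
    X<0, Y>0 -> WO (turnaround)     X<0, Y<0 -> WT (defensive)
    X>0, Y<0 -> ST (diversification)

The strategic intensities are U = |sum_O|*|sum_S| (positive side) and
V = |sum_T|*|sum_W| (negative side), and the intensity coefficient
rho = U/(U+V) in [0, 1] measures how strongly the positive side dominates;
rho > 0.5 supports an aggressive posture, otherwise conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateAnalysisError, MatrixValidationError

__all__ = [
    "StrategicQuadrilateral",
    "build_quadrilateral",
    "centroid",
    "azimuth",
    "strategic_intensities",
    "intensity_coefficient",
    "StrategyCall",
    "classify_strategy",
]


@dataclass(frozen=True)
class StrategicQuadrilateral:
    """Vertices of the strategic quadrilateral on the four semi-axes."""

    s_total: float
    w_total: float
    o_total: float
    t_total: float

    @property
    def vertices(self) -> tuple[tuple[float, float], ...]:
        """(S', O', W', T') as planar points, in counterclockwise order."""
        return (
            (self.s_total, 0.0),
            (0.0, self.o_total),
            (self.w_total, 0.0),
            (0.0, self.t_total),
        )

    @property
    def degenerate(self) -> bool:
        return self.s_total == self.w_total == self.o_total == self.t_total == 0.0


def build_quadrilateral(
    s_total: float, w_total: float, o_total: float, t_total: float
) -> StrategicQuadrilateral:
    """Place the four signed group totals on their semi-axes.

    Sign convention: S and O totals are >= 0, W and T totals are <= 0 (they
    arrive signed from the intensity stage).
    """
    if s_total < 0 or o_total < 0:
        raise MatrixValidationError(
            f"S/O totals must be non-negative, got S={s_total}, O={o_total}"
        )
    if w_total > 0 or t_total > 0:
        raise MatrixValidationError(
            f"W/T totals must be non-positive, got W={w_total}, T={t_total}"
        )
    return StrategicQuadrilateral(s_total, w_total, o_total, t_total)


def centroid(quad: StrategicQuadrilateral) -> tuple[float, float]:
    """Centroid (vertex average) of the quadrilateral: (sum x_i / 4, sum y_i / 4)."""
    xs = [v[0] for v in quad.vertices]
    ys = [v[1] for v in quad.vertices]
    return (sum(xs) / 4.0, sum(ys) / 4.0)


def azimuth(x: float, y: float) -> float:
    """Four-quadrant angle of (x, y) in degrees, counterclockwise in [0, 360)."""
    if x == 0.0 and y == 0.0:
        raise DegenerateAnalysisError("azimuth undefined at the origin")
    return math.degrees(math.atan2(y, x)) % 360.0


def strategic_intensities(quad: StrategicQuadrilateral) -> tuple[float, float]:
    """(U, V): products of the positive-side and negative-side total magnitudes."""
    u = abs(quad.o_total) * abs(quad.s_total)
    v = abs(quad.t_total) * abs(quad.w_total)
    return (u, v)


def intensity_coefficient(u: float, v: float) -> float:
    """rho = U/(U+V), in [0, 1]; undefined (error) when U + V = 0."""
    if u < 0 or v < 0:
        raise MatrixValidationError(f"intensities must be non-negative, got {u}, {v}")
    if u + v == 0:
        raise DegenerateAnalysisError(
            "strategic intensity coefficient undefined: U + V = 0 "
            "(all group intensities vanish on at least one axis pair)"
        )
    return u / (u + v)


@dataclass(frozen=True)
class StrategyCall:
    """The strategy classification: quadrant type plus intensity class."""

    quadrant_type: str  # "SO", "WO", "WT", "ST", or "X/Y" on a boundary
    intensity_class: str  # "aggressive" or "conservative"
    theta_deg: float
    rho: float
    boundary: bool = False
    message: str = ""


_QUADRANTS = {(1, 1): "SO", (-1, 1): "WO", (-1, -1): "WT", (1, -1): "ST"}
# adjacent quadrant pairs for axis-boundary centroids, keyed by (sign x, sign y)
_BOUNDARIES = {
    (0, 1): "SO/WO",
    (0, -1): "WT/ST",
    (1, 0): "SO/ST",
    (-1, 0): "WO/WT",
}


def classify_strategy(center: tuple[float, float], rho: float) -> StrategyCall:
    """Map the centroid quadrant and rho onto the SWOT strategy spectrum.

    Centroids on an axis are reported as boundary calls naming both adjacent
    types; rho > 0.5 classifies as aggressive, otherwise conservative.
    """
    x, y = center
    if x == 0.0 and y == 0.0:
        raise DegenerateAnalysisError(
            "strategy undefined: centroid at the origin (balanced analysis)"
        )
    intensity_class = "aggressive" if rho > 0.5 else "conservative"
    theta = azimuth(x, y)
    sx, sy = (x > 0) - (x < 0), (y > 0) - (y < 0)
    if sx == 0 or sy == 0:
        qtype = _BOUNDARIES[(sx, sy)]
        return StrategyCall(
            quadrant_type=qtype,
            intensity_class=intensity_class,
            theta_deg=theta,
            rho=rho,
            boundary=True,
            message=f"centroid lies on an axis: boundary between {qtype} strategies",
        )
    return StrategyCall(
        quadrant_type=_QUADRANTS[(sx, sy)],
        intensity_class=intensity_class,
        theta_deg=theta,
        rho=rho,
    )
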