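"""Report generation: fixed-precision summary tables, JSON and Markdown.

Published SWOT-AHP tables are stated at a fixed precision (4 decimals here;
azimuth to 2), and readers recompute downstream quantities *from the printed
values*: an intensity should equal the printed weight times the printed
strength, a total the column sum, the strategic vector the arithmetic on the
printed totals.  To make reports self-consistent in that sense, the summary
layer evaluates the whole downstream chain in fixed-precision decimal
arithmetic (round half away from zero at each published step):

- row geometric means are rounded, then normalized, to give the published
  weights;
- lambda_max comes from the full-precision weights and is rounded; CI is
  derived from the rounded lambda_max, and CR from that CI over RI;
- intensities multiply published weights by strengths; totals sum published
  intensities; the centroid, azimuth, U, V, and rho are derived from the
  published totals.

Full-precision results are kept on the analysis objects; this module only
controls what is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import DegenerateAnalysisError
from .intensity import GROUP_SIGNS
from .vector import azimuth, classify_strategy

__all__ = ["round_half_away", "GroupPrintInputs", "printed_summary", "write_report"]

_GROUP_ORDER = ("S", "W", "O", "T")


def _q(x: Decimal | float, ndigits: int) -> Decimal:
    d = x if isinstance(x, Decimal) else Decimal(repr(float(x)))
    return d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)


def round_half_away(x: float, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals (decimal, not binary)."""
    return float(_q(x, ndigits))


@dataclass(frozen=True)
class GroupPrintInputs:
    """Full-precision per-group quantities the printed chain starts from."""

    key: str
    ids: tuple[str, ...]
    labels: tuple[str, ...]
    geometric_means: np.ndarray
    lambda_max: float
    ri: float
    n: int
    strengths: tuple[float, ...]


def printed_summary(
    groups: Mapping[str, GroupPrintInputs],
    ndigits: int = 4,
    theta_digits: int = 2,
) -> dict[str, Any]:
    """Evaluate the fixed-precision report chain; returns a plain dict."""
    out: dict[str, Any] = {"groups": {}, "totals": {}}
    totals: dict[str, Decimal] = {}
    for key in _GROUP_ORDER:
        g = groups[key]
        gm_r = [_q(x, ndigits) for x in g.geometric_means]
        s = sum(gm_r)
        weights = [_q(x / s, ndigits) for x in gm_r]
        lam_r = _q(g.lambda_max, ndigits)
        if g.n <= 2:
            ci_chain = Decimal(0)
            cr = Decimal(0)
        else:
            ci_chain = (lam_r - g.n) / (g.n - 1)
            cr = _q(ci_chain / Decimal(repr(g.ri)), ndigits)
        sign = GROUP_SIGNS[key]
        intensities = [
            _q(sign * w * Decimal(repr(float(st))), ndigits)
            for w, st in zip(weights, g.strengths)
        ]
        total = _q(sum(intensities), ndigits)
        totals[key] = total
        out["groups"][key] = {
            "factors": [
                {
                    "id": fid,
                    "label": lab,
                    "weight": float(w),
                    "strength": float(st),
                    "intensity": float(inten),
                }
                for fid, lab, w, st, inten in zip(
                    g.ids, g.labels, weights, g.strengths, intensities
                )
            ],
            "lambda_max": float(lam_r),
            "ci": float(_q(ci_chain, ndigits)),
            "ri": g.ri,
            "cr": float(cr),
            "passes": float(cr) < 0.1,
            "total_intensity": float(total),
        }
        out["totals"][key] = float(total)

    x = _q((totals["S"] + totals["W"]) / 4, ndigits)
    y = _q((totals["O"] + totals["T"]) / 4, ndigits)
    u = _q(abs(totals["O"]) * abs(totals["S"]), ndigits)
    v = _q(abs(totals["T"]) * abs(totals["W"]), ndigits)
    if u + v == 0:
        raise DegenerateAnalysisError(
            "strategic intensity coefficient undefined: U + V = 0"
        )
    rho = _q(u / (u + v), ndigits)
    theta = _q(azimuth(float(x), float(y)), theta_digits)
    call = classify_strategy((float(x), float(y)), float(rho))
    out["strategic_vector"] = {
        "centroid": [float(x), float(y)],
        "theta_deg": float(theta),
        "U": float(u),
        "V": float(v),
        "rho": float(rho),
    }
    out["strategy_call"] = {
        "quadrant_type": call.quadrant_type,
        "intensity_class": call.intensity_class,
        "boundary": call.boundary,
        "message": call.message,
    }
    return out


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def _markdown(result: Any) -> str:
    p = result.printed
    nd = result.options.rounding
    lines: list[str] = [f"# {result.title}", ""]
    lines += [
        "## Group weights and consistency",
        "",
        "| Group | Factor | Weight | lambda_max | CI | RI | CR | Passes |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for key in _GROUP_ORDER:
        g = p["groups"][key]
        for k, f in enumerate(g["factors"]):
            diag = (
                f"{_fmt(g['lambda_max'], nd)} | {_fmt(g['ci'], nd)} | {g['ri']} | "
                f"{_fmt(g['cr'], nd)} | {'yes' if g['passes'] else 'NO'}"
                if k == 0
                else " |  |  |  | "
            )
            lines.append(f"| {key} | {f['id']} | {_fmt(f['weight'], nd)} | {diag} |")
    lines += [
        "",
        "## Factor intensities",
        "",
        "| Group | Factor | Weight | Strength | Intensity | Group total |",
        "|---|---|---|---|---|---|",
    ]
    for key in _GROUP_ORDER:
        g = p["groups"][key]
        for k, f in enumerate(g["factors"]):
            tot = _fmt(g["total_intensity"], nd) if k == 0 else ""
            lines.append(
                f"| {key} | {f['id']} | {_fmt(f['weight'], nd)} | {f['strength']:g} "
                f"| {_fmt(f['intensity'], nd)} | {tot} |"
            )
    sv = p["strategic_vector"]
    call = p["strategy_call"]
    lines += [
        "",
        "## Strategic vector",
        "",
        f"- Centroid (X, Y): ({_fmt(sv['centroid'][0], nd)}, {_fmt(sv['centroid'][1], nd)})",
        f"- Azimuth theta: {sv['theta_deg']:.{result.options.theta_rounding}f} deg",
        f"- Positive intensity U: {_fmt(sv['U'], nd)}",
        f"- Negative intensity V: {_fmt(sv['V'], nd)}",
        f"- Intensity coefficient rho: {_fmt(sv['rho'], nd)}",
        f"- Strategy call: **{call['quadrant_type']}**, {call['intensity_class']}"
        + (f" ({call['message']})" if call["boundary"] else ""),
        "",
    ]
    return "\n".join(lines)


def write_report(result: Any, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis result; ``format`` is ``"json"`` or ``"markdown"``.

    JSON output has stable key order and pinned rounding so identical inputs
    produce byte-identical files.
    """
    path = Path(path)
    if format == "json":
        doc = {"title": result.title, "analyst": result.analyst, **result.printed}
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    elif format == "markdown":
        path.write_text(_markdown(result))
    else:
        raise ValueError(f"unknown report format {format!r}")
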