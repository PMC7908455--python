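"""Plotting: the strategic quadrilateral and the polar strategy spectrum.

Headless-safe (Agg backend, no display needed); styling is deterministic so
regenerated figures are comparable across runs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)
import numpy as np  # noqa: E402

from .errors import DegenerateAnalysisError  # noqa: E402

__all__ = ["render_plots"]


def _quadrilateral_figure(result) -> plt.Figure:
    # draw at report precision so the figure matches the printed tables
    p = result.printed
    nd = result.options.rounding
    t = p["totals"]
    vertices = ((t["S"], 0.0), (0.0, t["O"]), (t["W"], 0.0), (0.0, t["T"]))
    verts = list(vertices) + [vertices[0]]
    xs, ys = zip(*verts)
    cx, cy = p["strategic_vector"]["centroid"]

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(xs, ys, "-o", color="tab:blue", zorder=3)
    ax.fill(xs, ys, color="tab:blue", alpha=0.15, zorder=2)
    names = ("S'", "O'", "W'", "T'")
    offsets = ((8, 4), (4, 8), (-8, -4), (-4, -12))
    for (vx, vy), name, off in zip(vertices, names, offsets):
        coord = f"{vx:.{nd}f}" if vy == 0 else f"{vy:.{nd}f}"
        ax.annotate(
            f"{name} ({coord})",
            (vx, vy),
            textcoords="offset points",
            xytext=off,
            fontsize=9,
        )
    ax.plot([cx], [cy], "s", color="tab:red", zorder=4)
    ax.annotate(
        f"P ({cx:.{nd}f}, {cy:.{nd}f})",
        (cx, cy),
        textcoords="offset points",
        xytext=(8, 8),
        fontsize=9,
        color="tab:red",
    )
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axvline(0, color="0.6", lw=0.8)
    ax.set_xlabel("internal axis:  W  <->  S")
    ax.set_ylabel("external axis:  T  <->  O")
    ax.set_title("SWOT strategic quadrilateral")
    ax.set_aspect("equal")
    return fig


def _spectrum_figure(result) -> plt.Figure:
    sv = result.printed["strategic_vector"]
    call = result.printed["strategy_call"]
    theta = np.deg2rad(sv["theta_deg"])
    rho = sv["rho"]

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.plot([theta, theta], [0.0, rho], "-", color="tab:red", lw=2)
    ax.plot([theta], [rho], "o", color="tab:red")
    ax.set_rmax(1.0)
    ax.set_rticks([0.25, 0.5, 0.75, 1.0])
    # rho = 0.5 separates aggressive from conservative postures
    circle = np.linspace(0, 2 * np.pi, 181)
    ax.plot(circle, np.full_like(circle, 0.5), "--", color="0.5", lw=1)
    for ang, name in ((45, "SO"), (135, "WO"), (225, "WT"), (315, "ST")):
        ax.text(
            np.deg2rad(ang), 1.08, name, ha="center", va="center", fontsize=12
        )
    ax.set_title(
        f"Strategy spectrum: theta = {sv['theta_deg']:.2f} deg, rho = {rho:.4f} "
        f"-> {call['quadrant_type']} ({call['intensity_class']})"
    )
    return fig


def render_plots(result, out_dir: str | Path, format: str = "svg") -> list[Path]:
    """Write the quadrilateral and spectrum figures; returns the file paths."""
    if result.quadrilateral.degenerate:
        raise DegenerateAnalysisError(
            "all group totals are zero: nothing to plot (degenerate quadrilateral)"
        )
    if format not in ("svg", "png"):
        raise ValueError(f"plot format must be 'svg' or 'png', got {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, make in (
        ("strategic_quadrilateral", _quadrilateral_figure),
        ("strategy_spectrum", _spectrum_figure),
    ):
        fig = make(result)
        path = out_dir / f"{name}.{format}"
        fig.savefig(path, metadata={"Date": None} if format == "svg" else None)
        plt.close(fig)
        written.append(path)
    return written
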