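#!/usr/bin/env python
"""Step 3: strategic quadrilateral, vector (theta, rho), and strategy call.

Places the four group totals on their semi-axes, takes the vertex centroid,
and computes the azimuth theta, intensities U and V, and the coefficient
rho = U/(U+V).  Writes the full JSON and Markdown reports plus the two
figures under results/.
"""

from pathlib import Path

from swotahp import bundled_example_path, load_config, run_full_analysis, write_report
from swotahp.plots import render_plots

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_full_analysis(load_config(bundled_example_path()))
    OUT.mkdir(exist_ok=True)
    write_report(result, OUT / "case_study_report.json", format="json")
    write_report(result, OUT / "case_study_report.md", format="markdown")
    files = render_plots(result, OUT / "figures", format="svg")
    sv = result.printed["strategic_vector"]
    call = result.printed["strategy_call"]
    print(f"centroid P(X, Y) = ({sv['centroid'][0]}, {sv['centroid'][1]})")
    print(f"azimuth theta = {sv['theta_deg']} deg")
    print(f"U = {sv['U']}, V = {sv['V']}, rho = {sv['rho']}")
    print(
        f"strategy call: {call['quadrant_type']} ({call['intensity_class']}) — "
        "pair internal strengths with external opportunities"
    )
    for p in [OUT / "case_study_report.json", OUT / "case_study_report.md", *files]:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
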