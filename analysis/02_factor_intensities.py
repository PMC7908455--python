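#!/usr/bin/env python
"""Step 2: signed factor intensities and group totals.

Multiplies each factor's AHP weight by its 0-5 estimated strength, signs by
group (S, O positive; W, T negative), and sums per group.  Writes
results/factor_intensities.csv.  The ranking of the four totals by magnitude,
printed below, feeds the strategic quadrilateral of step 3.
"""

import csv
from pathlib import Path

from swotahp import bundled_example_path, load_config, run_full_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_full_analysis(load_config(bundled_example_path()))
    OUT.mkdir(exist_ok=True)
    out = OUT / "factor_intensities.csv"
    with out.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "factor", "weight", "strength", "intensity", "group_total"])
        for key, g in result.printed["groups"].items():
            for i, f in enumerate(g["factors"]):
                writer.writerow([
                    key, f["id"], f["weight"], f["strength"], f["intensity"],
                    g["total_intensity"] if i == 0 else "",
                ])
    print(f"wrote {out}")
    totals = result.printed["totals"]
    ranked = sorted(totals, key=lambda k: abs(totals[k]), reverse=True)
    print("group totals:", ", ".join(f"{k}={totals[k]:+.4f}" for k in "SWOT"))
    print("importance ranking by |total|:", " > ".join(ranked))


if __name__ == "__main__":
    main()
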