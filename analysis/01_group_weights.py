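#!/usr/bin/env python
"""Step 1: AHP weights and consistency for the four SWOT groups.

Loads the bundled home-based-exercise configuration, computes
product-square-root weights and the consistency diagnostics per group, and
writes results/group_weights.csv.  All four matrices pass the CR < 0.1 test;
the dominant factors are the leading-sports-nation policy drive (S1), the
research/talent gap (W3), intelligent sports (O3), and fading post-epidemic
enthusiasm (T3).
"""

import csv
from pathlib import Path

from swotahp import bundled_example_path, load_config, run_full_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_full_analysis(load_config(bundled_example_path()))
    OUT.mkdir(exist_ok=True)
    out = OUT / "group_weights.csv"
    with out.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "factor", "weight", "lambda_max", "ci", "ri", "cr", "passes"])
        for key, g in result.printed["groups"].items():
            for i, f in enumerate(g["factors"]):
                diag = [g["lambda_max"], g["ci"], g["ri"], g["cr"], g["passes"]] if i == 0 else [""] * 5
                writer.writerow([key, f["id"], f["weight"], *diag])
    print(f"wrote {out}")
    for key, g in result.printed["groups"].items():
        top = max(g["factors"], key=lambda f: f["weight"])
        print(
            f"group {key}: lambda_max={g['lambda_max']:.4f}, CR={g['cr']:.4f} "
            f"({'passes' if g['passes'] else 'FAILS'}); "
            f"top factor {top['id']} (weight {top['weight']:.4f})"
        )


if __name__ == "__main__":
    main()
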