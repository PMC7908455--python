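# swotahp

Quantitative SWOT-AHP strategic analysis in Python.

A plain SWOT analysis lists an organization's Strengths, Weaknesses,
Opportunities, and Threats but says nothing about how much each factor
matters. This package implements the standard quantitative hybrid: the
Analytic Hierarchy Process (AHP) weights the factors inside each SWOT group
from expert pairwise comparisons, estimated strengths turn weights into
signed intensities, and a strategic vector condenses the four group totals
into a single, defensible strategy call. It ships a complete worked case
study — the development strategy of home-based exercise in China, assessed by
a ten-member expert panel — as a bundled configuration, and analyzes any
user-supplied SWOT configuration the same way.

Intended users: analysts and researchers running multi-criteria SWOT
assessments (public health, sports science, management) who want the
arithmetic reproducible, consistency-checked, and scriptable.

## The model

For each SWOT group, experts fill a pairwise comparison matrix
`A = (a_ij)` on the Saaty 1–9 scale (`a_ij` = importance of factor *i* over
factor *j*; `a_ji = 1/a_ij`). Priority weights use the product-square-root
(row geometric mean) method:

    gm_i = (prod_j a_ij)^(1/n),   w_i = gm_i / sum_k gm_k

The principal eigenvalue is estimated as
`lambda_max = (1/n) * sum_i (A w)_i / w_i`, giving the consistency index
`CI = (lambda_max - n) / (n - 1)` and the consistency ratio `CR = CI / RI`
(RI is the random index for order *n*); judgments are acceptable when
`CR < 0.1`.

Each factor's intensity is `(estimated strength, 0–5) x (weight)`, positive
for S and O, negative for W and T. The four group totals are placed on four
semi-axes (S: +x, W: −x, O: +y, T: −y) forming the strategic quadrilateral;
its centroid `P(X, Y) = ((ΣS + ΣW)/4, (ΣO + ΣT)/4)` yields the strategic
azimuth `theta = atan2(Y, X)` (strategy quadrant SO / WO / WT / ST), and the
intensity coefficient `rho = U / (U + V)` with `U = |ΣO|·|ΣS|`,
`V = |ΣT|·|ΣW|` grades the call aggressive (`rho > 0.5`) or conservative.

A synthetic-data module simulates expert panels (log-normal multiplicative
noise on judgments, optional snapping to the Saaty scale) so every stage is
testable without external data.

## Worked example

```sh
swotahp analyze $(python -c "import swotahp; print(swotahp.bundled_example_path())") \
    --out report.json --markdown report.md --plots figures
```

or in Python:

```python
from swotahp import bundled_example_path, load_config, run_full_analysis

result = run_full_analysis(load_config(bundled_example_path()))
print(result.printed["totals"])
print(result.printed["strategic_vector"])
print(result.printed["strategy_call"]["quadrant_type"])
```

which prints

```
{'S': 4.2112, 'W': -3.4786, 'O': 4.2901, 'T': -3.3144}
{'centroid': [0.1832, 0.2439], 'theta_deg': 53.09, 'U': 18.0665, 'V': 11.5295, 'rho': 0.6104}
SO
```

Reading: opportunities carry the largest total intensity (4.2901), followed
by strengths (4.2112); the weakness and threat sides are smaller in
magnitude. The centroid therefore lands in the first quadrant
(theta ≈ 53°), and the positive side dominates (rho = 0.6104 > 0.5): an
aggressive SO strategy — develop by pairing internal strengths with external
opportunities.

The numbered scripts under `analysis/` run the same case study step by step
(weights and consistency, intensities, strategic vector and figures, and a
noise-robustness study of the weighting stage) and write their tables under
`results/`.

Other CLI verbs: `swotahp check-matrix MATRIX.csv` validates a single
comparison matrix and prints weights and CR; `swotahp simulate` emits a
synthetic configuration for testing or sensitivity work.

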