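# Methods

## Scope and model

`swotahp` quantifies a SWOT analysis with the Analytic Hierarchy Process.
The hierarchy has three levels — goal, the four SWOT groups, factors within
each group — and the package operates at the factor level: one positive
reciprocal comparison matrix per group, judged on the Saaty fundamental
scale (1–9 and reciprocals; intermediate values are accepted with a warning,
or rejected under `strict_saaty`). No group-level comparison matrix is
modeled: the relative importance of the four groups is read off the
magnitudes of their total intensities rather than elicited separately.

### Weights

Weights come from the product-square-root method: the geometric mean of each
row, normalized to sum 1. Computation is done in log space, so large orders
and extreme judgment ratios do not overflow. For order 3 this is exactly the
principal-eigenvector solution (verified in the tests against a direct
eigen-solver); for higher orders it is the standard close approximation, and
the package uses it everywhere — an eigen-solver appears only as an
independent oracle in the test suite, never in the computation path.

### Consistency

`lambda_max` is estimated as `mean_i (A w)_i / w_i` with the geometric-mean
weights, which is exact for consistent matrices and `>= n` for any positive
reciprocal matrix. `CI = (lambda_max - n)/(n - 1)`; `CR = CI/RI` with the
random-index table for orders 1–10 (0, 0, 0.58, 0.90, 1.12, 1.24, 1.32,
1.41, 1.45, 1.49). Orders 1 and 2 are structurally consistent, so CR is
defined as 0 and passes; orders beyond 10 raise unless the caller supplies an
extended RI table. The pipeline gates on `CR < 0.1` per group — an error by
default, demotable to a warning — because downstream intensities are
meaningless when the weights themselves are untrustworthy.

### Intensities and the strategic vector

Factor intensity = estimated strength (a 0–5 magnitude; non-integers allowed)
× weight, signed positive for S/O and negative for W/T. Configurations that
carry pre-signed negative strengths for W/T are normalized to magnitudes with
a warning, since the sign belongs to the group, not the rating. Group totals
are convex combinations of strengths, hence bounded by 5 in magnitude.

The four totals are vertices on four semi-axes; the centroid is the plain
vertex average (division by 4). The azimuth uses the two-argument
arctangent mapped to [0°, 360°): a single-argument `arctan(Y/X)` cannot
separate quadrants I/III or II/IV, and the strategy typing needs all four.
The strategic intensities multiply absolute magnitudes, `U = |ΣO|·|ΣS|`,
`V = |ΣT|·|ΣW|`, so both are non-negative and `rho = U/(U+V)` lies in [0, 1].
The strategy taxonomy is the conventional quadrant map (SO / WO / WT / ST by
the centroid's signs) with an aggressive/conservative split at `rho = 0.5`;
centroids exactly on an axis are reported as boundary calls naming both
adjacent types, and a centroid at the origin (a perfectly balanced analysis)
is refused as undefined rather than silently classified.

## Fixed-precision report arithmetic

Internally everything is double precision. Reports, however, are stated at a
fixed precision (default 4 decimals; azimuth 2), and a reader should be able
to verify a report from its own printed numbers: each printed intensity must
equal printed weight × strength, each total the column sum, the strategic
vector the arithmetic on the printed totals. Output-only rounding breaks
this — e.g. rounding a weight down at the fourth decimal leaves an intensity
that no longer matches the printed product. The report layer therefore
evaluates the downstream chain in decimal arithmetic (round half away from
zero at every published step): geometric means are rounded, then normalized,
to give the published weights; `lambda_max` comes from the full-precision
weights and is rounded; CI derives from the rounded `lambda_max` and CR from
that CI; intensities, totals, centroid, azimuth, U, V, and rho each derive
from the published value of the previous step. Decimal (not binary) floats
are used here because half-way cases such as a centroid coordinate of
0.18315 must round by decimal rules. The full-precision values remain on the
result objects for anyone composing further computation; the two layers agree
to within one unit in the last printed digit.

## Synthetic expert panels

The generator emulates questionnaire elicitation. A true weight vector
defines the consistent matrix `a_ij = w_i/w_j`; each simulated expert
multiplies every upper-triangle judgment by `exp(eps)`,
`eps ~ N(0, sigma^2)` i.i.d. — the multiplicative log-normal model is the
natural sign-safe error structure for reciprocal ratio judgments — and the
lower triangle is set to exact reciprocals. Optional quantization snaps each
judgment to the nearest Saaty value in log space, ties resolving toward 1
(the conservative "equal importance" reading). Panels are aggregated by the
element-wise geometric mean of matrices (AIJ), the standard aggregation that
preserves reciprocity; how a real panel of judges should be condensed into
one matrix is a convention, and this is the one implemented. All randomness
derives from one master seed via numpy `SeedSequence` spawning with the
PCG64 generator, so panels and whole configurations are reproducible
bit-for-bit across platforms.

Default study conditions mirror the bundled case: group sizes (4, 3, 3, 3),
ten experts, integer strengths uniform on 0–5. A noise scale around
`sigma = 0.2` leaves almost all single judges under the CR threshold, while
`sigma = 0.6` fails roughly a third of them (see
`analysis/04_panel_robustness.py`).

What the generator does not emulate: systematic expert biases (anchoring,
halo effects), correlated errors across judges, incomplete questionnaires,
or any coupling between a factor's strength rating and its comparison
judgments. Passing tests on synthetic panels therefore demonstrate numerical
correctness and statistical behavior of the aggregation under independent
noise, not robustness to the failure modes of real elicitation.

## Numerical and design choices

- Reciprocity tolerance defaults to 1e-6 relative (survey-derived matrices
  may carry rounding); the diagonal is forced to exactly 1; a missing cell is
  filled from its mirror entry.
- Rounding is half away from zero, everywhere a value is published.
- The bundled case study runs in well under a second; the panel-robustness
  script simulates 600 judge matrices and 60 panel aggregations in a few
  seconds.
- The CLI exits 0 on success, 1 on validation/consistency failure, 2 on I/O
  or schema errors; plots use the Agg backend so headless runs need no
  display.
- Single-factor groups need no comparison matrix (weight 1, trivially
  consistent); matrices of order ≥ 2 are required otherwise.

## Known limitations

- No group-level AHP layer and no alternative prioritization methods (pure
  eigenvector, row sum, fuzzy AHP); no rank-reversal analysis.
- The strategy spectrum is classified only by quadrant and the rho = 0.5
  split; finer subdivisions sometimes drawn on SWOT strategy diagrams are
  not modeled.
- Estimated strengths are inputs; the package does not derive them from data.
- The aggressive/conservative threshold and the AIJ aggregation are
  documented conventions, not identified from any dataset.
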