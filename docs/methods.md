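# Methods

This note documents the models implemented in `fuzzrisk`, the conventions
chosen where the underlying formulations are open, and what the shipped
tests do and do not demonstrate.

## Triangular fuzzy numbers

All fuzzy quantities are triangular fuzzy numbers (TFNs) — ordered triples
(α, β, γ) with a piecewise-linear membership function peaking at the mode β.
Addition and multiplication are componentwise; multiplication (and scalar
scaling) is defined for non-negative supports only, which every shipped
linguistic scale satisfies. Construction rejects disordered triples; an
explicit `repair="sort"` mode re-sorts them, because silent reordering hides
data errors. Componentwise subtraction — needed only inside VIKOR — may
disorder a triple and is therefore performed with the repair mode; the
centroid (the mean of the three components) is invariant under that re-sort,
so late centroid defuzzification is unaffected.

Two defuzzifiers are exposed: the centroid mean (α+β+γ)/3 (the analytic
centroid of the triangle, verified against numeric integration in the test
suite) and the graded mean (α+4β+γ)/6 (also exposed under the name
`likert_mean` for expert-opinion triples; the two names share one formula).
The two coincide exactly when the triangle is symmetric about β. Fuzzy
maxima/minima and all "is greater" decisions use a total order: defuzzified
value first, ties broken by β, then α, then γ. The literature this package
follows does not state an ordering rule for fuzzy maxima; this one is
deterministic and reduces to the natural order for crisp numbers.

A garbled distance construction that appears alongside the TFN definitions
in the source material (its defining equation duplicates the addition rule)
is deliberately not implemented; only the graded-mean operator it references
is exposed.

## Linguistic scales

Defaults (JSON-overridable, `data/paper/scales.json`):

* severity: nine levels on [1, 10], "Very minor" (1,2,3) … "Dangerous
  without warning" (9,10,10);
* occurrence: the printed source table duplicates the severity wording, an
  apparent typesetting error, so the default occurrence scale reuses the
  same nine-level TFN ladder with occurrence-appropriate labels chosen to
  cover every occurrence label the worked example actually uses
  ("Very High", "High", "Moderate", "Low", "Remote");
* detection: five levels oriented so a *harder to detect* failure scores
  higher — "Very High [chance of discovery]" (1,1,3) up to "Remote"
  (8,10,10). The worked example uses two labels absent from this scale;
  they are resolved by aliases: "M" → "Moderate", and "Very Low" → "Low",
  the nearest listed category on the conservative side (mapping it upward
  to "Remote" would promote the affected modes against the reference
  ordering);
* output vocabulary: five levels VL…VH on [0, 1].

Label lookup is case-insensitive and alias-aware. A scale's entries must be
ordered by non-decreasing defuzzified value.

## Fuzzy FMEA

Expert ratings are aggregated per (failure mode, factor) as the
expert-weight-weighted componentwise mean; weights default to uniform and
are renormalised over the experts who actually rated the pair. The
multiplicative fuzzy RPN is the componentwise triple product, defuzzified
for ranking; the crisp value is also normalised by the scale maximum (1000
for 1–10 ladders) to locate the nearest output category (ties go to the
higher category — the assignment rule behind the printed joint outputs is
not stated in the source). Ranking is by descending crisp F-RPN with
competition ranks (ties share the minimum rank, stable by id); the same
tie rule is used by every ranking in the package.

## Mamdani inference

The engine implements exactly the classical operator set: min for AND (max
for OR), clipping (min) implication, pointwise-max aggregation over a
discretised output universe, and the discrete centroid Σxμ(x)/Σμ(x).
Input universes are [1, 10] for O/S/D, output [0, 1]; the default grid is
1001 points (≥ 100 enforced). TFN inputs are fuzzified at their centroid,
matching a workflow that aggregates the expert panel before inference.
Antecedents are unweighted (equal factor importance); rule weights are 1.

The rule base behind the published crisp outputs (0.930, 0.911, 0.750,
0.500) is unpublished, so those values are carried as reference data and are
not reproduction targets. `default_rule_base` generates a complete,
deterministic, monotone base: the consequent index is the rounded mean of
the antecedent terms' normalised ordinal positions, so all-top antecedents
map to the top output category and all-bottom to the bottom.

Two numerical caveats, both verified empirically and covered by tests:

* *Edge coverage.* The lowest O/S terms (1, 2, 3) have zero membership at
  x = 1 exactly, so the extreme corner of the universe fires no rule; the
  engine raises a dedicated error rather than fabricating an output.
* *Monotonicity.* Min–max–centroid inference is **not** globally monotone in
  its inputs even under a monotone rule base: at low firing strengths the
  clipped output set degenerates toward a rectangle whose centroid can
  exceed that of a more strongly clipped triangle (e.g. raising occurrence
  from 2.7 to 2.9 can lower the output by ~0.02 in fringe regions). On the
  category-mode lattice — each input at a term's modal value, where exactly
  one rule fires at strength 1 — monotonicity is exact, and that is where
  the property is asserted.

Grid convergence is tested at 101 vs 1001 points: the output moves by less
than half a coarse grid cell.

## Fuzzy MCDM rankers

All three rankers accept benefit and cost criteria; cost columns are
converted to benefit by the fuzzy reciprocal (1/γ, 1/β, 1/α) before
normalisation. For risk ranking all three FMEA factors are benefit
criteria (higher TFN = riskier), equal weights 1/3 by default.

Conventions for operations the fuzzy formulations leave open:

* *ARAS normalisation*: each TFN component is divided by the crisp
  (defuzzified) column sum including the appended ideal row. This preserves
  the TFN ordering, avoids span inversion, and is exact for crisp inputs —
  and is the main reason third-decimal agreement with the reference index
  table is not claimed (the reference's fuzzy-division dialect and full
  20-row inputs are not recoverable).
* *VIKOR*: fuzzy best/worst values per criterion come from the defuzzified
  total order; numerators use componentwise subtraction with repair;
  denominators are crisp (defuzzified) differences; weights are defuzzified
  before entering the regret maximum. S, R, Q stay fuzzy until a final
  centroid defuzzification, which (centroid linearity) guarantees
  Q ∈ [0, 1]. Constant criteria contribute zero with a warning; an
  all-constant matrix is an error. The compromise set follows the standard
  rule: if the acceptable-advantage condition fails, every alternative
  within 1/(m−1) of the best Q joins; if only the stability condition
  fails, the top two.
* *WASPAS*: columns are normalised componentwise by the fuzzy column
  maximum (so the maximal row maps to (1,1,1)); the weighted-product
  exponent uses the crisp weight. λ may be fixed (default 0.5, the
  conventional choice) or data-driven, λ = ΣP/(ΣQ+ΣP). The AM–GM
  inequality then guarantees WPM ≤ WSM per alternative.

v = 0.5 (VIKOR) and λ = 0.5 (WASPAS) are the package defaults, matching the
reference settings.

## Hybrid aggregation

The hybrid input is a failure-mode × method matrix of benefit indices in
[0, 1] (VIKOR entering as 1−Q). Ideal vectors are the per-column max/min
*of the index matrix itself* — this scoping reproduces the published
worked-example output exactly, where the formulation's notation is
ambiguous. Distances are unweighted Euclidean across method columns; any
number ≥ 1 of columns is accepted. UUI = ψ⁻/Σψ⁻ − ψ⁺/Σψ⁺; rows are ranked
by descending UUI with competition ties. Identities that hold by
construction — share sums equal 1, UUIs sum to 0, UUI ∈ [−1, 1] — are
enforced as tests on 1000 random matrices.

Reproduction tolerances: the packaged index matrix is printed to six
decimals, so recomputed distances can deviate from the printed ones by up
to ≈ 2·√3·5·10⁻⁷ ≈ 1.7·10⁻⁶ plus half a printed ulp; per-cell checks use
that bound, column sums twenty times it. Four failure modes carry
byte-identical index rows; their distances and UUIs are necessarily
identical and share one competition rank (the reference table prints
slightly inconsistent digits for one of them; the package asserts the
arithmetically consistent value).

## Synthetic registers

`SyntheticSpec` defaults mirror the study conditions: 20 failure modes,
5 experts, uniform expert weights, expert jitter of ±1 scale step. The
optional dominance chain assigns the first k modes strictly ordered grades
(k ≤ 9 to stay strict on nine-level ladders), giving a ground-truth order
that F-RPN, all three MCDM rankers and the hybrid stage must recover —
verified over 100 seeds at k = 5, 3 experts, zero noise. The generator
emulates ordinal linguistic ratings with categorical jitter only: it does
not model correlated expert biases, systematically missing ratings, or
inter-factor correlation, so passing tests demonstrate internal consistency
of the rankers, not robustness to those real-data features.

## Expert validation

Validation opinions are (optimistic, neutral, pessimistic) Likert triples
defuzzified by the graded mean; the packaged fixture carries the one fully
published expert block (all 20 defuzzified values reproduce to 2 d.p.). The
original study's bespoke convergence index is unpublished, so agreement is
reported through generic statistics: Spearman ρ, Kendall τ, top-k overlap,
and mean absolute rank difference. The default Likert mapping uses the odd
points 1/3/5/7/9, consistent with the observed values.

## Known limitations

* Only triangular fuzzy numbers (no trapezoidal/Gaussian shapes, alpha-cut
  interval arithmetic, or type-2 sets).
* The reference index-table values are ordering-level checks only (see ARAS
  note above); exact reproduction is claimed, and achieved, at the hybrid
  stage whose inputs are the printed indices themselves.
* Mamdani outputs depend on the (user-supplied or default) rule base;
  Sugeno-type inference and antecedent NOT are not implemented.
* The cause tally covers only the fully published register rows; the
  remaining modes' causes were never published.
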