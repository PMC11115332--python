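# fuzzrisk

Fuzzy FMEA scoring and hybrid fuzzy multi-criteria risk ranking for
healthcare (and other) failure-mode registers.

## The problem

Failure Modes and Effects Analysis (FMEA) prioritises risks by the Risk
Priority Number RPN = O × S × D, where Occurrence, Severity and Detection are
scored on 1–10 ordinal scales. In practice experts rate these factors with
words, not numbers, and different multi-criteria rankers applied to the same
register frequently disagree. `fuzzrisk` implements the full
linguistic-uncertainty pipeline used in fuzzy risk-assessment studies — the
motivating application is ranking 20 post-organ-transplant failure modes
(irregular immunosuppressant use, elapsed cold-ischemia time, …) rated by an
expert panel:

* **Triangular fuzzy numbers** (α, β, γ): componentwise algebra, membership,
  defuzzification by the centroid mean (α+β+γ)/3 and the graded mean
  (α+4β+γ)/6, and a defuzzified total order.
* **Fuzzy FMEA**: linguistic scales mapping labels to TFNs, weighted expert
  aggregation, the multiplicative fuzzy RPN
  F-RPN = S × O × D = (α₁α₂α₃, β₁β₂β₃, γ₁γ₂γ₃), and a Mamdani max–min
  inference engine (min implication, max aggregation, discrete centroid).
* **Three fuzzy MCDM rankers** over a TFN decision matrix:
  F-ARAS (utility degree Kᵢ = Sᵢ/S₀ against an appended ideal row),
  F-VIKOR (group utility Sᵢ, regret Rᵢ, compromise index
  Qᵢ = v(Sᵢ−S\*)/(S⁻−S\*) + (1−v)(Rᵢ−R\*)/(R⁻−R\*) with acceptable-advantage
  and stability conditions), and F-WASPAS (K′ᵢ = λ·WSM + (1−λ)·WPM).
* **Hybrid aggregation**: the per-method benefit indices (Kᵢ, 1−Qᵢ, K′ᵢ) form
  a matrix whose per-column maxima/minima define positive/negative ideal
  vectors η±; each failure mode's Euclidean distances ψ⁺, ψ⁻ to them are
  normalised by their column sums and differenced into the Ultimate Utility
  Index

  UUI = ψ⁻/Σψ⁻ − ψ⁺/Σψ⁺ ∈ [−1, 1],

  with higher UUI meaning higher risk priority. UUIs sum to zero over the
  register by construction.

The package ships the published worked example (linguistic scales, the
partially published risk register, the 20 × 3 index matrix, the expected
hybrid output, and one validation expert's Likert triples) as plain-text
fixtures, plus a seeded synthetic-register generator with a known dominance
chain for ground-truth testing.

## Worked example

Feed the packaged per-method index matrix straight into the hybrid stage:

```sh
python -c "from fuzzrisk.datasets import load_fixture; \
           load_fixture('method_indices').to_csv('indices.csv')"
fuzzrisk hybrid --indices indices.csv --precision 6
```

```
fm_id,psi_plus,psi_minus,uui,rank
FM1,0.0,1.154526,0.132746,1
FM2,0.609973,0.556958,0.022556,5
FM3,0.609973,0.556958,0.022556,5
FM4,0.885972,0.268699,-0.029358,13
FM5,0.797434,0.363281,-0.012462,12
FM6,0.247142,0.936935,0.09092,2
FM7,1.130652,0.036898,-0.07265,20
...
```

FM1 (irregular immunosuppressant use) holds every column maximum, so its
distance to the positive ideal is exactly 0 and it takes rank 1 with the
largest UUI (0.1327); FM6 (elapsed cold-ischemia time) follows. FM7 (heavy
post-transplant exertion) sits farthest from the ideals and ranks last.
FM2/FM3 (and FM12/FM13) have identical index rows, hence identical UUIs and
a shared competition rank.

The same ranking end-to-end from linguistic ratings:

```python
from fuzzrisk import *

register = load_fixture("transplant_register")   # 20 modes, 10 with ratings
matrix = build_matrix_from_register(register)    # O/S/D, equal weights 1/3
aras, vikor, waspas = aras_rank(matrix), vikor_rank(matrix), waspas_rank(matrix)
hybrid = ultimate_utility(to_benefit_indices(aras, vikor, waspas))
print(hybrid.ranking()[:3])                      # ['FM1', 'FM6', 'FM8']
```

Every stage is also a CLI subcommand (`score`, `mamdani`, `mcdm`, `hybrid`,
`simulate`, `validate`, `run`); see `fuzzrisk --help`.

## Scope notes

The Mamdani rule base and the expert-agreement index used in the original
study are unpublished; `fuzzrisk` ships a deterministic monotone default
rule base and generic rank-agreement statistics (Spearman ρ, Kendall τ,
top-k overlap) instead, and carries the published inference outputs as
reference data only. See `docs/methods.md` for the full method description,
numerical conventions and limitations.
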