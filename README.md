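# pinedemog

Stage-structured demographic analysis of pine caterpillar (*Dendrolimus
spectabilis*) branch censuses: field counts → stage densities → life table
→ single-loop projection matrix → growth rate, stable stage structure,
sensitivities/elasticities → perturbation sweeps. A seeded synthetic-census
generator makes the whole chain testable without any field data.

## The problem and the model

The pine caterpillar is a univoltine defoliator of Korean pines. Its
censusable life cycle is a single loop of six stages — eggs (E), four
larval classes (L1 newly hatched autumn larvae, L2 autumn larvae before
overwintering, L3 early-spring larvae after diapause, L4 late-spring
larvae) and pupae (P). Branch surveys (30 trees × 2 branches per date,
counts per 1000 cm² of branch surface, with surface ≈ length × diameter)
give stage densities *n_x*, from which the life table follows:

- survival into each stage: *g_x = n_x / n_{x−1}*
- cumulative survivorship: *l_x = n_x / n_a*
- realized fecundity: *F = n_a*, the observed egg density (adults cannot
  be censused on branches, so egg density stands in for reproduction).

These parameterize a 6×6 Lefkovitch-type matrix **A** with the five
survivals on the subdiagonal and *F* in the top-right corner. The life
cycle graph is one directed 6-cycle, so **A** is irreducible but
imprimitive with index 6: all six eigenvalues share the modulus
(*F*·∏*g*)^(1/6). The asymptotic per-step growth rate λ is the unique
positive real eigenvalue, taken by dense eigendecomposition (power
iteration never converges on such a matrix). Sensitivities are
*s_ij = v_i w_j / ⟨v, w⟩* and elasticities *e_ij = (a_ij/λ) s_ij*; on a
single loop every structural elasticity is exactly 1/6, so *sensitivities*
(absolute effects) carry the comparative information. One-at-a-time sweeps
replace each survival with values 0.1–1.0 (step 0.1) and fecundity with
50–500 (step 10) and locate the smallest value with λ > 1.

## Worked example

```python
from pinedemog import build_matrix, eigen_analysis, printed_life_table

model = build_matrix(printed_life_table())
eig = eigen_analysis(model)
print(round(eig.lambda_, 4))       # 0.7435
print([round(x, 3) for x in eig.w])
```

Running `python examples/printed_table_analysis.py` prints (abridged):

```
lambda (per stage transition) = 0.7435
Stable stage structure (asymptotic composition):
    E: 0.7987   L1: 0.0978   L2: 0.0710
   L3: 0.0143   L4: 0.0096    P: 0.0086
Structural sensitivities (effect of each transition on lambda):
   E->L1: 1.3617   L2->L3: 0.8261   L3->L4: 0.2478
  L1->L2: 0.2295    L4->P: 0.1878        F: 0.0018
```

λ ≈ 0.74 < 1 means the censused population was declining (each year
multiplies density by λ⁶ ≈ 0.17). The stable structure says eggs dominate
the standing composition; the sensitivity ranking says λ responds most to
survival of newly hatched larvae (E→L1) and of overwintered larvae
(L2→L3) — the two smallest survivals in the loop. The sweeps
(`python examples/perturbation_sweeps.py`) show that only those two
transitions, or a fecundity above 420 eggs per 1000 cm², can lift λ above
1; exactly 3 of the 6 swept parameters have a crossing.

Other examples: `simulate_census.py` (synthetic season → re-estimated
life table) and `recovery_check.py` (bias/RMSE of the estimators over
replicated surveys).

## Command line

Each pipeline stage is independently runnable and chains through the
documented CSV schemas:

```bash
pinedemog simulate --seed 1 --out census.csv
pinedemog densities census.csv --out density.csv
pinedemog report --printed-table
```

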