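# Methods

## Census protocol and density units

A census record is one branch on one date: tree id, canopy position
(upper/lower), branch length and diameter in cm, and counts of eggs,
larvae and pupae. Stage density is `count / (length × diameter) × 1000`,
i.e. individuals per 1000 cm² of branch surface, with surface area taken
as the plain length × diameter product — a rectangle proxy, kept exactly
as the survey defines it, with no cylindrical (π) correction. Larval
instars are not distinguishable on the branch; a larval count is assigned
to a life-cycle stage later, by its survey date.

Per-date summaries are mean ± SE over sampling units. The default unit is
the branch (n = trees × branches per tree per date); `by_tree=True`
averages the two branches within each tree first and takes the SE over
tree means. The branch-level default is the simplest reading of a
"mean ± SE per branch" convention; whether upper/lower branches should be
pooled per tree first is genuinely ambiguous, so both are exposed. A
single sampling unit yields SE = 0 with a logged warning rather than NaN.

## Life table

For ordered stage densities `n_x` (stages E, L1, L2, L3, L4, P):
`g_x = n_x / n_{x−1}`, `l_x = n_x / n_a` with `n_a` the egg density, and
realized fecundity `F = n_a`. Two identities are maintained at machine
precision: `l_x` equals the running product of the `g_x`, and the product
of all `g_x` telescopes to `n_P / n_E`. The first density must be
positive; a zero density followed by a positive one is rejected
(resurrection); a trailing zero is allowed (the cohort died out).
Apparent `g_x > 1` — possible under census noise — is accepted with a
logged warning, never clipped. Eggs-per-egg-mass (mean 169, range
139–265) is kept as a documented constant for biological context; the
matrix fecundity is always the realized egg density.

Two parameterizations are provided:

- **raw-density path** — ratios recomputed from the densities as given;
  with the published densities this yields a pupal survival of 0.64
  (0.16/0.25) and λ = 0.7368;
- **printed-table mode** (`printed_life_table()`) — survivals pinned at
  their published two-figure values (0.091, 0.54, 0.15, 0.50, 0.66),
  F = 69.45. The published pupal figure (0.66) was evidently formed from
  unrounded densities, so pinning is the only way to replicate the
  published matrix bit-for-bit; λ = 0.7435, printing as 0.74 either way.
  Sweep thresholds are grid-sensitive, so this mode is the default
  baseline for sweeps.

Stage calendar windows map density series to stages; defaults encode the
observed season (eggs 1998-08-05; L1 1998-08-19; L2 mid-October; L3 at the
first post-winter survey, 1999-03-14; L4 mid-May; P early July) and are
fully configurable. Dates are opaque ordering keys — no interpolation
between surveys.

## Projection matrix and eigen-analysis

The 6×6 matrix has the five survivals on the subdiagonal and F in the
top-right corner; adult survival and oviposition are absorbed into that
corner entry (no explicit seventh adult class — this reproduces all
published quantities, and the published stable-structure labels, which are
shifted by one against the stage list, match the E…P positional ordering
used here). One matrix application advances one stage transition; six
applications make one year, so λ is reported per step (0.74) with the
annual rate λ⁶ alongside.

Because the nonzero pattern is a single 6-cycle, the matrix is
imprimitive: all six eigenvalues lie on a circle of radius
(F·∏g)^(1/6), and power iteration cannot converge. The implementation
uses `numpy.linalg.eig` and selects the eigenvalue with zero imaginary
part (tolerance 1e-9, scaled) and positive real part. The closed form
(F·∏g)^(1/6) is deliberately *not* used by the implementation; it serves
as the independent oracle in the tests (equivalence is property-tested
over random loop matrices at 1e-9 relative tolerance).

`w` (stable stage distribution) is the right eigenvector normalized to
sum 1; `v` (reproductive value) the left eigenvector with first entry 1;
`S = v wᵀ / ⟨v, w⟩` is kept as a full matrix, with the six structural
entries reported for bar-style summaries (each survival labelled by its
destination stage, fecundity by E). `eigen_analysis` verifies both
eigen-equations to 1e-9 before returning. Elasticities are
`(A/λ) ∘ S`; on a single loop every structural elasticity is 1/6 exactly,
which doubles as a numerical self-check.

Recomputed `w` differs from the published vector in the last printed digit
at two positions (0.0978 vs 0.097; 0.0086 vs 0.0085), presumably because
the authors used unrounded survivals; comparisons there allow one unit in
the last printed digit and are exact elsewhere.

## Perturbation sweeps

Sweeps are one-at-a-time replacements (not multipliers): each survival
takes the grid values 0.1–1.0 step 0.1 read as absolute probabilities,
fecundity 50–500 step 10, endpoints inclusive, everything else at
baseline. The threshold is the smallest grid value with λ strictly
greater than 1; with the printed-table baseline the fecundity threshold is
420 (λ ≈ 1.0036 there; the unrounded crossing point is 1/∏g ≈ 411.1, and
λ = 1 exactly never occurs on the grid, so strict vs non-strict is moot in
practice). λ is strictly monotone in every loop parameter, so thresholds
are unique and grid refinement can only move the fecundity threshold down
toward 411.1 — both are property-tested.

## Synthetic census generator

The generator emulates the survey design: per date, 30 freshly chosen
trees × one upper + one lower branch; branch length ~ U(25, 45) cm and
foliage-cylinder diameter ~ U(10, 20) cm — the measured "diameter" of a
sampled pine branch is that of its needle cylinder, so a typical branch
offers ~350–900 cm² of surface, the same order as the 1000 cm² reporting
unit. The default calendar assigns one survey date to each stage (the six
dates listed above); dates on which no stage of the focal generation is
active would add only structural zeros and are omitted by default, while
the date list remains fully configurable.

Counts per branch are negative binomial with mean `density × area / 1000`
and dispersion k (variance m + m²/k). The survey reports only means ± SE,
so the count distribution is an assumption, not an inference: k = 1 is
the default — strong overdispersion typical of clustered insect counts —
and k = ∞ gives the Poisson limit. Upper and lower canopy share the same
true density (no canopy effect is simulated). An optional clustered-egg
mode draws egg masses (NB) and eggs per mass (uniform on 139–265) instead
of independent eggs; the default is unclustered.

What the generator does not emulate: spatial correlation among trees,
weather-driven mortality pulses, observer error in branch measurement, and
within-date stage mixtures. Passing recovery tests therefore show that the
*estimators* are consistent under the stated sampling model, not that real
surveys are unbiased.

`recovery_experiment` runs the full pipeline per replicate (child seeds
drawn below 2³¹ from the config seed) and reports bias and RMSE of each
ĝ_x, l̂_x and λ̂ against the generator truth. A replicate that samples an
intermediate stage at zero density but a later one positive cannot form a
life table and is dropped and counted (`n_failed`; ~0 under defaults); a
replicate whose *final* stage samples at zero has a broken loop and
contributes λ̂ = 0, which is the correct value for a loop with a zero arc.
With defaults (Table-style truth, 200 replicates) mean λ̂ sits within
about 0.015 of the truth; the late-loop survival ratios (ĝ_L4, ĝ_P) are
individually noisy because few pupae occur per branch, but λ̂ depends only
on the loop product and is well-behaved. Problem sizes used in the test
suite (200 replicates of 360 branch records; 1000 random matrices for the
eigensolver property) run in a few seconds.

## Numerical conventions

- All internal arithmetic at full double precision; rounding only at
  presentation (λ to 2 decimals, survivals and w to 2 significant
  figures), using round-half-even.
- Eigenvalue realness tolerance 1e-9 (scaled by the spectral radius);
  eigen-equation residual check 1e-9.
- Degenerate inputs: empty record sets, empty stage windows, non-positive
  branch dimensions, negative or fractional counts, broken loops and
  resurrecting density sequences all raise `ValueError` with the offending
  field, stage or row named; pipeline errors are prefixed with the stage
  (census/lifetable/projection/sweep) that produced them.

## Known limitations

- Single-sex, density-independent, deterministic projection: no transient
  indices (meaningless under imprimitivity — all eigenvalues share the
  modulus), no stochastic environments, no multi-parameter perturbations.
- The life table conflates cohorts across one observed season, as the
  underlying survey design does.
- SE propagation stops at the density stage; the life-table ratios carry
  no analytic uncertainty — use `recovery_experiment` for sampling
  distributions instead.
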