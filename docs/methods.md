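# Methods

## Setting and assumptions

`X` and `Y` are binary exposure and outcome; `Z` is a categorical
instrument, by default the three genotype values `{0, 1, 2}` of a SNP; `U`
is an unmeasured confounder. Writing `Y_x` for the potential outcome under
exposure `x` (SUTVA assumed), the package works under the standard IV
assumption set:

- **A1 relevance** — `Z` is associated with `X`;
- **A2 independence** — `Z ⊥ U`;
- **A3 exclusion restriction** — the instrument affects the outcome only
  through the exposure (`Y_{z,x} = Y_x`);
- **A4 conditional ignorability** — `Y_x ⊥ (Z, X) | U`.

No potential treatment `X_z` is assumed; nothing is assumed about the law
of `X` given `(Z, U)` beyond A1. The estimand is the average treatment
effect `ATE = E[Y₁ − Y₀]`, a risk difference in `[−1, 1]`.

In a **two-sample design** only `P(X=1|Z=z)` and `P(Y=1|Z=z)` are
observed (from two independent studies); in a **one-sample design** the
joint `P(X=x, Y=y|Z=z)` is observed. Population-level probabilities are
assumed throughout: the package quantifies what the *design* can and
cannot reveal, separately from estimation error. The bounds never depend
on the genotype frequencies `P(Z=z)`; those enter only the
summary-statistic conversion and the simulation models.

## Sharp bounds

**Linear-programming route (any design, 2–4 levels).** A latent
*response-type distribution* assigns mass `q(y₀, y₁, x | z)`. A2 + A4
imply the `(y₀, y₁)`-marginal is the same at every `z`; the data enter as
matching constraints (joint cells for one-sample, the two marginals for
two-sample). Minimizing/maximizing `P(Y₁=1) − P(Y₀=1)` over this polytope
(HiGHS via `scipy.optimize.linprog`; 4 + 8·K variables for K levels)
yields sharp bounds: any feasible point is realizable by an explicit DGP
with `U = (Y₀, Y₁)`, so the program's range *is* the identification
interval. An infeasible program means the data are incompatible with
A1–A4 — the strongest possible observable falsification.

**Closed form (two-sample, 2–3 levels).** The two-sample bounds are the
max (lower) and min (upper) of five linear expression families — three
ranging over ordered level pairs, two over single levels. The family set
is closed under the label-switching symmetries (`Y → 1−Y` maps lower
families to upper families; `X → 1−X` with `ATE → −ATE` permutes them),
which pins every coefficient, and the implementation is verified against
the LP on random IV-consistent tables to 1e−8 in both endpoints
(property-tested at n = 1,000). Crossed results (`upper < lower`) are returned unmodified — they
are diagnostic, and empirically coincide with LP infeasibility.

**Falsification inequalities.** Two nontrivial families over ordered
level pairs (12 constraints for three levels) plus probability-range
checks. They are necessary but *not* sufficient for compatibility with
A1–A4 when the instrument has more than two levels: on uniform random
tables that pass them, the closed-form bounds still cross for ≈0.8% of
all raw draws (≈1.4% of the accepted tables). Both denominators are
reported because "fraction of distributions tried" is ambiguous; the
raw-draw figure is the headline number. Every stored crossing instance
passes the inequalities and is LP-infeasible.

**Length.** For a table with strength
`ST = max_{z≠z'} |P(X=1|Z=z) − P(X=1|Z=z')|`, the bound length is at most
`2 − 2·ST`, and the bound is attained. The attainment search
(`max_length_at_strength`) exploits that level permutations leave the
bounds invariant, so `P(X=1|Z=z)` can be taken increasing with range
exactly `ST`; all remaining constraints and the objective are then linear,
and the supremum is computed exactly as an LP with auxiliary envelope
variables `l ≤ lower`, `u ≥ upper`. At `ST = 0.5` it returns 1.0 to
machine precision.

**Aggregation.** Intersection bounds (valid if all instruments valid),
union bounds (valid if at least one is), and a nesting check (sorted by
length, each interval contains the next; tolerance defaults to 1e−10 and
should be widened to the Monte Carlo error when the inputs are simulated).

## Summary-statistics conversion

For a SNP with exposure log-OR `γ̂`, outcome log-OR `Γ̂`, effect-allele
frequency `f` and prevalences `P(X=1)`, `P(Y=1)`: genotype frequencies
default to Hardy–Weinberg `((1−f)², 2f(1−f), f²)`; the intercept solves
`Σ_z expit(γ₀ + γ̂z) P(Z=z) = P(X=1)` by Brent's method on a bracket
guaranteed to change sign (the left side is strictly increasing in `γ₀`),
to |residual| < 1e−12; then `P(X=1|Z=z) = expit(γ₀ + γ̂z)` and
analogously for the outcome. The marginal GWAS log-OR is used directly as
the per-genotype slope — a good approximation when instruments are
independent and effects small, which is the regime of real GWAS; no
attenuation correction is attempted. Reconstructed marginals always
average back to the input prevalences (property-tested).

## Simulation models

Exposure: `logit P(X=1|Z=z, U=u) = γ₀ + Σᵢ γᵢ zᵢ + γ_U u` with
`U ~ N(0,1)`. Outcome: `logit P(Y=1|X=x, Z=z, U=u) = β₀ + β_X x + β_Z z +
β_U u`, with `β_Z = 0` under a valid instrument and `β_Z ≠ 0` for
pleiotropy. Genotypes are independent with the balanced distribution
`(0.25, 0.5, 0.25)` by default.

Numerical conventions:

- All one-dimensional confounder integrals use 64-node Gauss–Hermite
  quadrature (error ≪ 1e−12 for bounded integrands such as expit) —
  marginals, ATE, strength curves are therefore deterministic.
- With `p > 1` instruments, the others are marginalized by Monte Carlo:
  one shared draw of `(Z ∈ {0,1,2}^p, U)` serves every instrument and
  conditioning level (only the `γⱼZⱼ` term is swapped), with a fixed seed
  and common random numbers across levels. Default 10⁶ draws; a warning
  is logged below 10⁴.
- Intercept conventions: `γ₀ = −γ₁` for one instrument and
  `γ₀ = −Σᵢγᵢ` for several (each instrument has mean 1 under the balanced
  genotype law, so the linear predictor is centred); `β₀ = −β_X/2` in the
  power-style studies.

Derived analyses and their defaults:

- `st_to_gamma1`: inverts the strictly increasing map `γ₁ ↦ ST(γ₁)` by
  Brent's method. At target 0.5 it gives 1.101, 1.158, 1.315, 1.783 for
  `γ_U` = 0.1, 0.5, 1, 2 — instrument effects (odds ratios of 3–6) far
  beyond typical GWAS hits.
- `smallest_gamma_excluding_zero`: first grid hit on `(0, 8]` (33-point
  grid) refined by bisection to 1e−4; a qualifying `γ₁` must give a
  non-crossed bound that excludes 0 on the side of `sign(β_X)` while
  covering the model's true ATE. Returns none under a null effect. The
  result is decreasing in the effect size and increasing in confounding
  (property-tested).
- Multi-instrument scenarios: the four genetic architectures (many weak;
  many strong; very weak plus one medium; medium plus one strong `γ_p=4`)
  at `p` = 10 or 50. The confounder coefficients for this study are not
  pinned down by the single-instrument analyses; the package uses
  `γ_U = β_U = 0.1` as the scenario default, under which per-scenario
  bounds are nested (so intersection = strongest instrument) and exactly
  one configuration — scenario 4, `p = 10`, `β_X = 1`, the `γ = 4`
  instrument — excludes zero. At unit confounding that single informative
  bound instead straddles zero by ≈0.03, so conclusions there are
  sensitive to the assumed confounding scale.
- Pleiotropy grid: `β_X ∈ {−2…2}`, `β_Z, γ₁ ∈ {−0.5…0.5}` (7 values
  each), `γ_U = β_U = 1`. Across all 245 cells the bounds cover the true
  ATE and the falsification inequalities never fire: weak instruments
  produce bounds so wide that moderate exclusion-restriction violations
  are invisible to every observable check.
- Dichotomized continuous exposure: `X̃ = γ₁Z + γ_U U + ε` with standard
  normal noise (the noise law is a package choice), `X = 1[X̃ ≥ median]`,
  outcome driven by the continuous `X̃`. Plug-in frequency estimates of
  the marginals (no smoothing). Default 10⁷ simulated observations;
  tests and the bundled experiment grid use 10⁶, where the sign property
  (a zero-excluding bound always agrees with `sign(β_X)`) holds across
  the full grid.

## Design comparison (covariance sampling)

Each conditional covariance `Cov(X,Y|Z=z)` is confined to a closed
interval by cell validity of the reconstructed joint, and each pairwise
difference `Cov(z) − Cov(z')` to another interval by the one-sample
falsification inequalities. Two samplers are provided:

- `rejection` (default): uniform on the per-level boxes, rejecting
  pairwise violations — uniform over the feasible polytope, the flat-prior
  reading;
- `sequential`: level 0 uniform on its interval, subsequent levels
  truncated to the currently feasible range — not uniform over the
  polytope, but matching a sequential-sampling description.

For each sampled triple the joint is reconstructed and the one-sample LP
bound computed. Joints the LP rejects (the pairwise constraints do not
exhaust the IV constraints — for the worked examples 7–20% of draws) are
excluded from denominators and counted. On the bundled worked examples
with 10⁴ draws, the fraction of one-sample bounds excluding zero is ≈0%
(A1), ≈26% (A2) and ≈36% (A3, with bounds on both sides of zero); the two
samplers agree to within ~2 percentage points, sequential slightly closer
to the reference figures, which is what `scripts/acceptance.py` reports.
Every sampled one-sample bound lies inside the two-sample bound of the
same marginals. The multi-instrument variant samples per-instrument
covariance triples independently (derived seed streams) and intersects
the per-draw bounds.

These summaries are *plausibility* statements under the chosen sampling
scheme, not probabilities that a one-sample study would be informative.

## Synthetic data and what the tests show

There is no real genotype data anywhere: marginal tables are either drawn
uniformly with falsification-inequality rejection, produced by the
logistic models above, or reconstructed from random latent response-type
distributions (which are IV-consistent by construction and provide ground
truth ATEs for containment tests). This exercises the full identification
logic but none of the finite-sample issues of real MR data — sampling
error in summary statistics, LD between SNPs, allele harmonization,
non-HWE genotype frequencies, winner's curse. Passing tests therefore
certify the identification and diagnostic machinery, not robustness to
estimation noise; confidence intervals for estimated bounds are
deliberately out of scope.

## Known limitations

- Closed-form bounds cover 2–3 instrument levels only; 4 levels go
  through the LP.
- Binary exposure and outcome only; the continuous-exposure path detects
  signs after dichotomization, nothing more.
- The LP is exact but not vectorized; screening millions of tables uses
  the closed form, with the LP reserved for oracle checks and one-sample
  computations.
- `sequential` sampling is order-dependent (levels 0 → 1 → 2) and its
  induced distribution over the feasible polytope is not uniform.
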