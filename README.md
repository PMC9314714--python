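# mrbounds

Nonparametric bounds on the average treatment effect (ATE) for
**two-sample summary-data Mendelian randomization** (MR).

Most two-sample MR analyses fit parametric models to GWAS summary
statistics. `mrbounds` instead asks what can be said about the causal
effect of a binary exposure `X` on a binary outcome `Y` *without*
parametric assumptions, using a SNP genotype `Z ∈ {0, 1, 2}` as an
instrument, when `P(X=1|Z=z)` and `P(Y=1|Z=z)` come from two separate
studies and the joint law of `(X, Y)` is never observed. It is aimed at
MR methodologists and applied analysts who want to know, before or after
running a study, whether a bound-based analysis can possibly be
informative.

## What it computes

Under the core IV assumptions — relevance, independence of the instrument
from the confounder `U`, exclusion restriction, and conditional
ignorability given `U` — the package provides:

- **Sharp two-sample bounds** on `ATE = P(Y₁=1) − P(Y₀=1)` in closed form
  for 2- and 3-level instruments, and by an explicit linear program over
  latent response-type distributions for any of 2–4 levels (one-sample and
  two-sample designs). The LP doubles as an independent oracle for the
  closed form and as a strictly stronger falsification check: an
  infeasible program means no data-generating process satisfying the IV
  assumptions can produce the observed probabilities.
- **IV (falsification) inequalities** with per-constraint slacks, and
  "crossed" bounds (`upper < lower`) reported as-is — both are diagnostics
  of instrument invalidity.
- **Instrument strength** `ST = max_{z≠z'} |P(X=1|Z=z) − P(X=1|Z=z')|`,
  the concentration parameter `μ² = ST²/4 · Σzᵢ²/σ²`, and the sharp length
  bound `2 − 2·ST` (two-sample bounds are only guaranteed shorter than 1
  when `ST > 0.5`).
- **Summary-statistics conversion**: per-SNP log odds ratios, effect-allele
  frequency and study prevalences → the conditional probabilities the
  bounds need, via intercept solving under Hardy–Weinberg genotype
  frequencies.
- **Confounded simulation models**: logistic exposure/outcome models with
  a shared standard-normal confounder (optionally pleiotropic), strength
  curves `ST(γ₁)`, multi-instrument scenarios with intersection/union/
  nesting analysis, and a continuous-exposure model with median
  dichotomization for sign detection.
- **Design comparison**: the unidentified conditional covariances
  `Cov(X, Y|Z=z)` are sampled over their feasible polytope, joints are
  reconstructed via
  `P(X=x,Y=y|Z=z) = P(X=x|Z=z)P(Y=y|Z=z) + (2·1[x=y]−1)·Cov(X,Y|Z=z)`,
  and one-sample sharp bounds are computed for each draw — quantifying how
  much a one-sample design could have revealed that the two-sample design
  cannot.

## Worked example

```python
import mrbounds as mrb

# a SNP with exposure log-OR 0.8, outcome log-OR 0.1, allele frequency 0.5,
# exposure prevalence 50%, outcome prevalence 10%
record = mrb.GwasRecord("rs1", gamma_hat=0.8, big_gamma_hat=0.1,
                        eaf=0.5, prev_x=0.5, prev_y=0.1)
m = mrb.marginals_from_summary(record)
print("P(X=1|Z=z) =", m.p_x.round(3))
print("P(Y=1|Z=z) =", m.p_y.round(3))
print("ST =", round(mrb.instrument_strength(m.p_x), 3))
b = mrb.two_sample_bounds(m)
print("ATE bounds = [%.3f, %.3f], length %.3f" % (b.lower, b.upper, b.length))
print("IV inequalities pass:", mrb.iv_inequality_check(m).passed)
```

prints

```
P(X=1|Z=z) = [0.31 0.5  0.69]
P(Y=1|Z=z) = [0.091 0.1   0.109]
ST = 0.38
ATE bounds = [-0.401, 0.419], length 0.820
IV inequalities pass: True
```

Even this implausibly strong instrument (`ST = 0.38` is orders of
magnitude beyond real GWAS instruments, whose strengths are typically
below 0.01) leaves an interval of length 0.82 that comfortably covers
zero — the central cautionary message. The design-comparison framework shows what
a one-sample study could have added:

```python
s = mrb.plausible_one_sample_bounds(mrb.worked_example("A2"),
                                    n=10_000, seed=1)
print("%.1f%% of plausible one-sample bounds exclude 0"
      % (100 * s.frac_excluding_zero))
```

```
26.7% of plausible one-sample bounds exclude 0
```

The same operations are available from the shell:

```sh
mrbounds from-summary --input snps.tsv --prev-x 0.5 --prev-y 0.1 --output marginals.tsv
mrbounds bounds --input marginals.tsv --aggregate intersect
mrbounds design-compare --input marginals.tsv --n 500 --seed 1
mrbounds experiment --name crossing --seed 1
```

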