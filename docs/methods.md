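# Methods

## The question the package answers

Can a small feed-forward neural network recover the shape of a
gene–environment interaction from balanced case-control data better than
standard logistic regression?  The package implements the full simulation
machinery needed to answer that question: generative penetrance models with a
controlled population prevalence, case-control sampling, a from-scratch
multilayer perceptron (MLP) trained by resilient backpropagation with BIC
topology selection, logistic-regression competitors under two genotype
codings, and a grid-based mean-absolute-difference fit statistic with
empirical prediction bands.

## Generative risk models

A biallelic locus `G ∈ {0,1,2}` (number of mutated alleles, Hardy–Weinberg
equilibrium at minor allele frequency `maf`, default 0.30) and an exposure
`U ~ Uniform[0,100]` drawn independently of `G` determine disease through a
penetrance function `F(g,u) = P(Y=1 | G=g, U=u)`:

* **Sigmoid (Amato-type) models** `F(g,u) = z / (1 + exp(α_g + β_g u))` with
  four members — genetic (`β = 0`, `α` varies with `g`), environmental
  (`α` constant, `β` constant ≠ 0), additive (both effects), interaction
  (`α` constant, `β` varies with `g`).  High- and low-risk scenarios halve
  `α₁` resp. `β₁`.
* **Masking models 1–4** — piecewise models in which exactly one genotype
  class follows a sigmoid `1/(1+exp(−r(u−50)))` in the exposure (risk
  increase `r` = 0.150 high / 0.075 low) while the other classes sit at
  constants built from a baseline risk `c` (0.05 for models 1–2, 0.075 for
  3–4).  Model 1: sigmoid for `g=0`, `c` otherwise.  Model 2: `z·sigmoid`
  for `g=0`, `c` / `2c` for `g=1` / `2`.  Model 3: mirror of model 1 with
  the sigmoid on `g=2`.  Model 4: `c/2`, `c`, and `(z−2c)·sigmoid + 2c`.
* **Null model** — constant `F = K` (no association).

### Prevalence calibration

Each model carries a scale `z` chosen so the population prevalence
`K = Σ_g P(g) · (1/100)∫₀¹⁰⁰ F(g,u) du` equals 0.10.  The exposure average
of every sigmoid has a closed form via the softplus antiderivative
(`∫ expit(−(a+bu)) du = −softplus(−(a+bu))/b`), and the prevalence is affine
in `z` for every built-in family, so the calibration `z = (K − B)/A` is
exact; a Brent bisection fallback covers user-defined families.  Calibrated
values at `maf = 0.30` (high/low): genetic 0.886/0.390, environmental
0.200/0.200, additive 0.177/0.178, interaction 0.171/0.169, masking 1–4
0.254, 0.286, 0.631, 0.964 — reproduced by `gxemlp calibrate` and asserted
to ±0.001 in the tests.  Two readings of the parameter table were fixed by
the calibration itself: the genetic/additive intercepts are `(2/3)α₁` and
`(4/3)α₁`, and the first branch of masking model 4 is `c/2` — only these
reproduce the calibrated bounds above.

### Case-control conversion

Under balanced outcome-dependent sampling (case fraction `π = 1/2`) the
within-sample disease probability is

    f(g,u) = π F (1−K) / [ π F (1−K) + (1−π)(1−F) K ].

The theoretical `K` of the generating model is used, not the empirical
prevalence of a finite population, since the surface represents a perfectly
drawn sample.  The conversion is validated empirically: binned case shares
of two-step case-control draws match `f` within Monte-Carlo error.

## Sampling

Two equivalent routes produce case-control data:

1. **Two-step design** — simulate a population (default 5 × 10⁶ subjects;
   one uniform draw per subject against `F(g,u)` assigns status), then
   sample `n` cases and `n` controls without replacement per stratum.
2. **Direct conditional sampler** — rejection-sample `(g,u)` from
   `P(g,u | Y=1)` and `P(g,u | Y=0)` against `F` and `1−F`.

The two routes are distributionally identical; the test suite checks this
with two-sample Kolmogorov–Smirnov tests on the exposure and genotype
frequency comparisons per stratum against a five-million-subject population.
Replicated experiments default to the direct sampler, which avoids
materializing the population.  Output rows are shuffled so downstream fits
never see status-sorted data.

## The perceptron

At most one hidden layer (a single hidden layer suffices for piecewise
continuous functions), logistic activation everywhere, cross-entropy error
(the exact negative Bernoulli log-likelihood), inputs fed raw (genotype
0/1/2 and exposure 0–100, no standardization).  With `m = 0` the network is
algebraically a logistic regression in genotype and exposure — the package
exploits this as a cross-validated oracle: rprop-trained `m = 0` weights
must match IRLS coefficients to 1e−3 and the BIC to 1e−6.

**Training** is full-batch rprop+ (sign-based per-weight step sizes with
weight backtracking): same gradient sign multiplies the step by `η⁺ = 1.2`
(capped at `Δmax = 50`), a sign flip multiplies by `η⁻ = 0.5` (floored at
`Δmin`), reverts that weight's last update and zeroes its stored gradient.
Training stops when `max|∂E/∂w| ≤ 0.01` or after `stepmax` iterations
(default 10⁵).  Starting weights are i.i.d. standard normal; each topology
is restarted 5 times.

*Step-size floor.* `Δmin` defaults to 1e−9 rather than the conventional
1e−6.  With raw exposures the error curvature along the exposure weight
reaches ~10⁶, so a 1e−6 floor cannot resolve the 0.01 gradient bound: the
optimizer enters a permanent step/revert 2-cycle a few ×10⁻⁴ away from the
optimum.  At 1e−9 the same fits converge in a few hundred iterations.

**Topology selection.**  Widths `m = 0..5` are each trained from
`n_restarts` random starts and the fit minimizing `BIC = 2E + p log N`
(`p = (n+1)m + m + 1` weights, `p = n+1` for `m=0`) is selected, ties broken
toward fewer weights and then lower error.  Runs that stop at the iteration
cap still compete (their error is a valid likelihood); only diverged runs
(non-finite error) are excluded.  `converged_only=True` restricts the pool
to converged runs.  The inclusive default matters at reduced step budgets,
where the best fits are often the ones that have not yet pushed the gradient
norm under the threshold; at the full 10⁵-step protocol the two policies
coincide because nearly every run converges.

## Logistic-regression competitors

Five candidates per genotype coding — null, exposure-only, gene-only, both
main effects, full (mains + interaction) — fitted by IRLS (statsmodels GLM,
binomial family) and selected by the same BIC.  Co-dominant coding enters
the allele count as one column (full model: one `count × exposure` term);
design-variable coding uses heterozygous/homozygous indicators (full model:
two interaction terms).  Interaction-only models are excluded (hierarchy).
(Quasi-)separation is flagged when any coefficient exceeds 50 in magnitude
and the fit is kept.

## Evaluation

Predictions are evaluated on the fixed grid `u′ = 0, 0.1, …, 100`
(1001 points) for `g = 0, 1, 2`:

    E_{g,u′} = (1/K_rep) Σ_k | f(g,u′) − f̂ₖ(g,u′) |,

summed over all 3 × 1001 cells into the scalar fit statistic.  Pointwise
95% prediction bands are the 3rd and 98th ordered predictions at 100
replicates (generally the `ceil((K_rep+1)·0.025)`-th and
`floor((K_rep+1)·0.975)`-th order statistics, which reduce to (3, 98) at
`K_rep = 100`).  Coverage is reported both strictly (all 3003 cells, ties
inclusive) and as the covered fraction.  For a single observed data set,
pointwise 95% bootstrap percentile bands over refits to resampled rows are
available (`bootstrap_band`).

## Study orchestration and reproducibility

The full matrix is 8 models × 2 scenarios × 3 sample sizes (1000+1000,
500+500, 200+200) × 100 replicates, plus the null model and a maf = 0.05
sensitivity profile.  Per-situation seeds are SHA-256 hashes of
(seed_base, model key, sample size); per-replicate data and training streams
derive from them, so execution order cannot change results and reruns are
byte-identical.  When the two-step route is requested, one population per
(model, scenario, maf) is shared across sample sizes.

## Desk-scale profile

Training the full protocol (stepmax 10⁵, 5 restarts, 6 topologies, 100
replicates) is a multi-hour computation per situation.  The packaged
desk-scale profile (`DESK_TRAIN_CONFIG`) keeps the 5 restarts and all six
topologies but caps rprop at 2000 iterations; past that point the gradient
norm keeps shrinking while the fitted surface is essentially stationary.
The test suite runs the method-ranking comparison at 20 replicates with this
profile and the null-association topology check at 100 replicates with a
lighter screening profile (stepmax 1000, 2 restarts), whose outcome was
verified insensitive to the step budget.  At these sizes the qualitative
ranking of methods is stable, but the perceptron's summed-E values sit above
the fully-trained ones (e.g. masking model 2 scores ≈ 140 instead of ≈ 118),
so desk-scale totals should be read as upper bounds on the MLP column.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: HWE genotypes,
uniform exposure, independence of the two factors, Bernoulli status from a
calibrated penetrance, balanced strata.  It does not model confounders,
missing data, genotyping error, non-uniform (e.g. bell-shaped) exposures,
linkage, or covariate-dependent sampling — conclusions from passing tests
therefore concern the idealized design, not any particular real cohort.

## Numerical choices and limitations

* Sigmoids are evaluated saturation-safely; predicted probabilities are
  clipped to `[1e−12, 1−1e−12]` inside the error only — gradients use the
  exact residual `μ − y`.
* Gradient correctness is property-tested against central finite
  differences on non-saturated instances; at float saturation finite
  differences of the clipped error are uninformative by construction.
* BIC ties are broken deterministically (fewer parameters, lower error,
  earlier run), so reruns select identical models.
* The direct sampler's acceptance rate equals the prevalence (cases) or its
  complement (controls); degenerate specs with zero acceptance raise.
* The genetic/additive sigmoid models follow the parameter table literally:
  `α` increases with `g`, so the mutated genotype has the *lower* risk
  plateau.  The package does not re-interpret the intended effect direction.
* Only uniform exposures and the nine built-in families are provided;
  penetrance models are never fitted to data (the generative layer is not an
  estimator).
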