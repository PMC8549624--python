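# Methods

## The model

`daphtox` fits a robust Bayesian binomial generalized linear mixed model
for acute-toxicity survival in a common-garden experiment with *Daphnia
magna* from urban and rural ponds. The observation unit is one jar of
N_i = 5 (exceptionally 6) neonates scored for survival after 48 h of
exposure to a solvent control or the organophosphate insecticide
chlorpyrifos, at 20 °C or 24 °C:

    y_i ~ Binomial(N_i, p_i)
    logit(p_i) = β0 + CPF_i·βCPF + URB_i·βURB + T_i·βT
               + CPF_i·URB_i·βCPF:URB + CPF_i·T_i·βCPF:T + URB_i·T_i·βURB:T
               + CPF_i·URB_i·T_i·βCPF:URB:T
               + CPF_i·b_pop(i) + CPF_i·b_clone(i)

All three treatment variables are coded ±0.5 (chlorpyrifos/urban/24 °C
= +0.5), so the intercept is the average condition and interaction
columns are exact products of main-effect codes. Both random effects are
**multiplied by the signed pesticide code**: a population or clone
deviation describes differential *sensitivity to the pesticide*, raising
survival in one arm and lowering it in the other by equal logit amounts.
The model equation is implemented literally with the ±0.5 multiplier; a
configuration flag (`ModelData(units, scale_by_cpf=False)`) offers the
alternative 0/1-indicator reading, off by default, because the coding
statement and the equation only pin down the signed version.

Population effects are Gaussian, b_pop ~ Normal(0, σ_pop). Clone effects
use a Student-t distribution, b_clone ~ StudentT(ν, 0, σ_clone), whose
degrees of freedom ν are estimated: with small ν the distribution's fat
tails absorb outlying clones without inflating σ_clone; as ν → ∞ it
reduces to the Gaussian. Priors are weakly informative:

- β_j ~ StudentT(3, 0, 5) for all eight coefficients, the intercept
  included (the coefficient vector is treated uniformly);
- σ_pop, σ_clone ~ half-StudentT(3, 0, 5);
- ν ~ Gamma(shape 2, **rate** 0.1), mean 20. The shape–rate convention
  matters — shape–scale would put the prior mean at 200 and silently
  change the robustness behaviour.

The likelihood includes the binomial coefficient. It cancels in
inference but makes unit tests against closed forms exact.

## Sampling

No probabilistic-programming backend is used: the sampler module is a
self-contained dynamic Hamiltonian Monte Carlo implementation (NUTS with
multinomial state selection along the doubling trajectory, biased toward
the fresh subtree), with

- dual-averaging step-size adaptation toward a 0.9 target acceptance
  rate (conservative, chosen for the funnel-like geometry of the
  hierarchical scales; overridable),
- windowed diagonal mass-matrix estimation during warmup (initial 75 /
  terminal 50 iteration buffers with doubling estimation windows,
  shrunk proportionally for short warmups),
- divergence flags for trajectories whose energy error exceeds 1000,
- a maximum tree depth of 10.

Sampling happens on an unconstrained vector: random effects are
non-centered (b = σ·z with z standard Normal resp. standard Student-t),
and σ_pop, σ_clone, ν are log-transformed with Jacobian terms. The
log-density gradient is derived analytically and evaluated by a
numba-compiled kernel; a pure-numpy reference implementation of the same
density and gradient is kept and the two are cross-checked in the test
suite (along with a finite-difference check of the gradient itself).

Defaults reproduce the reported scheme: 4 chains × 10,000 iterations,
first 5,000 discarded as warmup, leaving 20,000 retained draws. Warmup
draws never appear in the output and adaptation never runs after warmup.
Chain c draws from an independent substream of the single seed
(`numpy` `SeedSequence` spawning), so chains are individually
reproducible. Initialization draws unconstrained coordinates uniformly
from [−2, 2] (the `zero` strategy additionally pins random effects at
0), retrying up to 100 times for a finite log-density.

Scaled-down settings used by the heavyweight validation runs (the
acceptance tests, the acceptance script and the recovery experiments)
are 4 chains × 1,500–2,000 iterations with half discarded as warmup.
These sizes give bulk ESS in the high hundreds to thousands for every
fixed effect on the 392-unit design, which is ample for median/CrI
summaries; they are the package's default desk-scale choice.

## Convergence diagnostics

R-hat is the rank-normalized **split** potential scale reduction factor
and ESS the rank-normalized bulk effective sample size, delegated to
arviz, which implements the modern formulation the R-hat < 1.01
criterion refers to; plain Gelman–Rubin is deliberately not offered so
the criterion cannot silently drift. A parameter with zero variance
across all draws raises a labelled `DegenerateParameterError` rather
than reporting a misleading 1.0. Divergence counts are reported per
chain; draws restored from a source without divergence flags yield an
explicit "not applicable", never a silent zero.

## Synthetic data

The generator emulates the experimental structure exactly: 2
urbanization classes × 5 populations × 5 clones × 2 pesticide × 2
temperature × 2 replicates = 400 jars, with one clone (u2.5) fully
excludable (392 jars) and k jars (default 4) started with 6 instead of 5
neonates. Because the as-run record does not identify *which* jars held
six neonates, the generator designates the first k jars in deterministic
design order — reproducibility beats realism here, and the loader
accepts either value anywhere. One integer seed derives three
independent substreams (population effects, clone effects, binomial
outcomes), so enlarging one stage never perturbs the others and
identical seeds give bit-identical datasets.

The `paper_like` preset sets the fixed effects and variance components
to the posterior medians reported for the study data (βCPF = −7.86,
βCPF:URB = 1.91, βURB = −0.35, βT = −1.01, βCPF:T = 1.02, βURB:T = 0.84,
βCPF:URB:T = −1.24, σ_pop = 1.25, σ_clone = 1.12, ν = 14.76). The
intercept is not reported anywhere and is **derived** so the control-arm
marginal survival equals 99.90%: β0 = logit(0.9990) + 0.5·βCPF ≈ 2.977
(the control arm carries the −0.5 code). Recovery claims about β0
therefore refer to this derived value only. The `null` preset zeroes
every effect with β0 = 2 and keeps small positive random-effect scales
(0.5) so the hierarchical model remains identified when refit to its own
output; `strong_interaction` doubles βCPF:URB.

What the generator does *not* emulate: the temporal death process within
48 h, feeding/husbandry, dose–response across concentrations, or any
clone-level correlation structure beyond the exchangeable Student-t. A
passing recovery experiment therefore shows the inference machinery is
calibrated *for data matching the model's assumptions*; it cannot
certify the model against real-data misspecification — that is what the
posterior predictive checks on a fitted dataset are for.

## Marginal effects and summaries

Posterior summaries are medians with 80%/95% equal-tailed credible
intervals; quantiles use linear interpolation between order statistics
(the numpy default), which matters for interval endpoints of small draw
sets and is therefore fixed and documented. Sign probabilities count
draws of the stated sign, with ties at exactly zero counted half.

"Marginal effect at the mean values of the other variables" is
operationalized as: the variable(s) of interest set to their ±0.5 codes,
every other centered code at 0, and all random effects at 0 (the average
condition, population and clone). Contrasts (e.g. the chlorpyrifos
effect in percentage points) are computed **per draw** and then
summarized — never as a difference of summaries, since medians do not
compose. Contrasts are emitted on both the percentage-point and the
proportion scale because published reports mix the two. Note that the
difference of the logits of two reported marginal medians need not equal
the reported coefficient median exactly for the same reason; the
implementation never asserts that composition.

## Posterior predictive checks

Each check thins the retained draws evenly to `n_replicates`, simulates
y_rep ~ Binomial(N, p) for every unit using that draw's own fixed *and*
random effects, and compares observed against replicated discrepancy
statistics, reported as tail probabilities Pr(T(y_rep) ≥ T(y_obs)). The
statistics — per-arm mean and per-arm variance of unit-level survival
fractions, plus the distribution of per-unit survivor counts (0–6) —
are this package's choice of defaults targeting the quantities this
design estimates; the reference analysis does not name its statistics.

## Prior sensitivity

`prior_sensitivity` refits the model under a list of `PriorSpec`
variants with the same seed policy and tabulates each fixed effect's
median and 95% CrI side by side with the maximum absolute median shift
per parameter. Individual fit failures are reported per specification
without aborting the comparison.

## Numerical choices and edge cases

- `inverse_logit` is scipy's `expit`; likelihood terms use the
  log1p/logaddexp forms so survival probabilities of ~1e−300 never
  underflow in log space.
- ν has support (0, ∞) exactly as its Gamma prior implies; no artificial
  lower bound. Values of ν < 2 make the clone-effect variance infinite
  while the density stays proper — a documented footgun, not an error.
- σ = 0 is allowed only in the generator (degenerate scale for tests),
  never inside the model, whose support is σ > 0.
- The compiled kernel's digamma uses the standard
  recurrence-plus-asymptotic-series evaluation; it agrees with scipy to
  ~1e−9 in the gradient, far below MCMC noise.
- Draw persistence uses 17-significant-digit CSV plus a JSON sidecar and
  round-trip float parsing, so `save → load` is lossless.

## Known limitations

- **Quasi-separation at near-certain survival.** Under the realistic
  preset the control arm survives at 99.90%, so a sizeable fraction of
  synthetic replicates contain zero control-arm deaths. The control-arm
  logit β0 − 0.5·βCPF is then bounded from below but not above by the
  likelihood, and the upper side of its posterior is governed by the
  weakly informative priors. In those replicates the equal-tailed
  intervals for β0 and βCPF sit above/below their generating values, and
  frequentist coverage of the 95% CrI for these two parameters drops to
  roughly two-thirds (the other six fixed effects and both scales remain
  at nominal-ish coverage). This is a property of the design at these
  survival rates — the posterior is stable under 4× longer chains — and
  is shared by any Bayesian analysis of such data, not a defect of the
  sampler.
- The sampler is sequential; chains are not run in parallel.
- No alternative link functions and no overdispersion mechanisms beyond
  the two random effects.
- Real-data reproduction of the published posterior requires the
  deposited dataset, which this package does not bundle; the
  self-contained validation surface is synthetic-data based.
- R-hat/ESS inherit arviz's conventions (e.g. minimum draw counts); very
  short chains can produce NaN diagnostics, surfaced as a failed
  convergence flag rather than hidden.
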