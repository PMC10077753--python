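# Methods

## The scientific problem

Female ungulates in montane systems trade forage quality against offspring
safety: while provisioning a dependent neonate they tend to shift toward
rugged, steep, secure terrain and away from the productive habitat they
prefer when pregnant or after losing a lamb. `reprorsf` implements a
resource-selection analysis in which that shift is explicit: selection
coefficients jump at parturition and relax back to baseline as the neonate
grows.

## Model

Used GPS locations are contrasted with available points in a
use-availability (RSF) design. For animal *i*, day *j*, observation *k*:

    logit(p_ijk) = beta_0 + sum_n beta_n,ij * X_n,ijk

with a coefficient process per habitat covariate *n*:

    beta_n,ij = (1 - Lamb_ij) * beta_n_base
              + Lamb_ij * f(beta_n_base, gamma_n, Part_ij, sigma_n)

`Lamb` indicates a live dependent neonate, `Part` is days since
parturition, `gamma_n` the immediate post-parturition offset and `sigma_n`
the half-normal scale (days) of the return. Two decay forms are
implemented, selected by `decay_mode`:

* `baseline_return` (default): `beta_base + gamma * exp(-Part^2 / (2 sigma^2))`
  — the coefficient relaxes to its baseline, which is how the return rates
  are described and tabulated;
* `literal_zero`: `(beta_base + gamma) * exp(-Part^2 / (2 sigma^2))` — the
  process equation taken literally, under which the whole coefficient
  decays to zero selection.

Both agree at `Part = 0` (`beta_base + gamma`). Because `sigma` acts as a
half-life-like scale, reported "adjusted" return times are `2 * sigma`.

### Likelihoods: pooled Bernoulli and matched conditional logit

The reference protocol fits the pooled Bernoulli (logistic) likelihood over
all used and available rows with a single intercept. That estimator has a
structural limitation this package documents rather than hides: under a
fixed 10:1 availability design the true within-stratum log-odds is
`beta_t' x − log(10 * E_f[exp(beta_t' x)])`, so the implied intercept moves
with `Part` whenever coefficients do. A single shared intercept cannot
absorb it, and the post-parturition offset `gamma` is attenuated (roughly
halved in our validation scenario) even though windowed per-period fits
recover the decay curve exactly.

The package therefore also implements the matched **conditional-logit**
likelihood (`likelihood="matched"`): each used fix and its own available
points form one choice set, the intercept cancels, and the time-varying
normaliser is handled exactly. For data generated by the weighted-candidate
movement model this estimator is correctly specified, and it is the one the
validation studies use. The Bernoulli likelihood remains the default
everywhere (stepwise selection, the Bayesian top-model fit, the
post-mortality model) because it is the reference protocol.

## Synthetic study system

No collar data ship with the package, so a generator reproduces the study
conditions and provides ground truth.

**Landscape** (`grids`): elevation is a spectral Gaussian random field
(power-law filter `|k|^-(1+2*roughness)`, default roughness 0.7) rescaled
exactly to 1400–2800 m on a 10-m grid. Slope uses the Horn 3x3 kernel
(edges linearly extrapolated); ruggedness is the classic Sappington VRM
(1 − |resultant unit normal| / n over a 3x3 window) — the "localized"
refinement cited in the source is not recoverable from it and is out of
scope. Distance to water is straight Euclidean distance to the nearest of
a few random perennial sources (a cost-distance hook is left to callers).
Vegetation covers (annual/perennial herbaceous, shrub, tree; percent) are
correlated blends of z-scored terrain drivers plus smoothed noise, by
default negatively tied to slope/ruggedness for herbaceous classes —
steep, rugged ground is forage-poor, which is what creates the tradeoff.
Rasters are exchanged as ESRI ASCII grids (plain text, cell-centre
coordinates, row 0 = north).

**Reproduction** (`movement.simulate_timelines`): parturition day-of-year
~ Normal(102, 15) rounded to days (a mid-April centre, typical of desert
bighorn lambing), neonate death geometric with daily hazard 0.006 censored at
120 days — front-loaded mortality with ~50% survival to weaning.

**Movement** (`movement.simulate_fixes`): 6 fixes/day at 02:00–21:00 clock
slots chosen so the 04–10 h and 13–22 h subsampling windows are exercised.
At each fix, candidates are drawn uniformly from the disc of radius
2.58 x `step_sd_m` around the previous fix and one is kept with weight
`exp(X beta(t))`; the coefficient path is evaluated by the same
`model.beta_t` used in fitting, so the generative and inferential models
share code. Fixes are thinned (default miss probability 0.05, chosen so a
simulated fleet resembles collars that pass the >90% fix-rate screen) and
flagged 2-D with probability 0.05. The candidate count (default 50; the
validation scenario uses 400) and `step_sd_m` are documented sensitivity
knobs.

**What the generator does not emulate**: serially correlated step
direction (home-range fidelity), habitat-dependent fix failure,
multi-animal interaction, seasonal vegetation change. Passing tests show
the estimation machinery recovers parameters from data that obey the
model's assumptions; they do not certify behaviour on field data that
violate them.

## Data preparation

Filters run in a fixed order, each reporting counts: fix-rate screen
(strictly > 0.90 achieved/scheduled), 2-D fix removal, daily subsampling
(at most two fixes per window, "first" rule by default; a seeded random
rule is available), reproductive labelling (`Lamb = 1` from parturition
through `min(death_day − 1, 120)`). Provisioning rows past 120 days are
excluded as weaned. Post-mortality rows go to dataset2 only for females
losing the neonate within 30 days; later losses contribute pre/provisioning
rows to dataset1 but no dataset2 rows (the most conservative reading of the
exclusion rule).

The availability radius is `2.58 x SD` (ddof = 1) of within-animal
consecutive step lengths — the literal reading of "SD x 2.58", not
mean + 2.58 SD. Available points (10 per used fix, exactly) are drawn
uniformly over the **pooled** availability domain, the union of discs of
that radius around all used fixes clipped to the landscape; a
`per_point` mode (each stratum uniform on its own disc) is retained. The
pooled design matches "buffering all locations" and, unlike per-point
discs, does not over-sample habitat near each used fix (per-point
availability measurably attenuates strong coefficients). Covariates are
sampled at the containing 10-m cell and z-scored over the combined
used + available rows by default; precomputed (e.g. landscape-global)
scalers can be supplied, which the validation studies do so that fitted
coefficients are on the simulation-truth scale.

A greedy correlation screen removes covariates until no retained pair has
|Pearson r| >= 0.7 (threshold configurable), dropping from the worst pair
the member with the larger mean absolute correlation to the rest.
`tradeoff_regressions` quantifies the risk-prone vs risk-averse structure
of the landscape with per-pair OLS slopes and R².

## Estimation

**ML** (`model.fit_ml`): L-BFGS-B on the chosen likelihood with `sigma`
on the log scale (bounds 0.5–300 days), `gamma` started at 0.2 so the
`sigma` direction is identified at the start. Deterministic given data and
init; non-convergence and |beta| > 15 (separation symptom) are flagged.

**Model selection**: AICc = −2 logL + 2k + 2k(k+1)/(n−k−1). Backward
stepwise treats a covariate's `(gamma, sigma)` block as separable from its
base coefficient; candidates are evaluated in alphabetical order for
determinism, the intercept is never dropped. The default rule drops a term
when *keeping* it fails to improve AICc by more than 2 (the
uninformative-parameter convention); a `strict_improvement` rule (removal
must itself lower AICc by the threshold) is available. Under the default
rule a true-zero covariate survives only when its chi-square(1) deviance
exceeds ~4, so it is dropped in ~95% of replicates.

**Bayesian fit** (`bayes`): priors Normal(0, variance 10) on intercept,
base coefficients and offsets — the precision reading of a "variance 0.1"
prior, selectable as literal variance or SD via `PriorSpec` — and
Uniform(1, 60) on each `sigma` (60 is vague because doubling it spans the
120-day provisioning window; the lower bound is configurable down to
0.001). The sampler is an in-package adaptive random-walk Metropolis with
three blocks (betas, gammas, sigmas); each block's proposal scale adapts
toward 30% acceptance during burn-in and is frozen afterwards, preserving
detailed balance for the retained draws. Chains (default 3) start from
over-dispersed jitter around the ML fit, with per-chain seeds spawned from
the master seed. Reference protocol: 20,000 iterations with 1,000 burn-in;
the reduced default scenario uses 4,000/1,000.

**Diagnostics**: classic Gelman–Rubin Rhat per parameter
(`sqrt(((n−1)/n W + B/n)/W)`, no rank-normalisation or chain-splitting),
threshold 1.1 (warn or error). Trace data are exported for plotting rather
than visually assessed in-package.

**Summaries**: posterior mean, 0.025/0.975 quantiles, percent of draws
above/below zero (ties counted once, on the non-positive side), and the
overlap of each post-parturition state with the Pre distribution — by
default the overlapping coefficient (integrated minimum of the two
Gaussian KDEs), with a CrI-containment alternative; the method is recorded
in the output. Return-rate tables report `sigma` and `2 sigma`.
Coefficient trajectories evaluate `beta_t` per posterior draw for days
0–120 (day −1 = baseline) and report pointwise medians and 95% CrIs.

**Post-mortality model** (`bayes.fit_mortality_model`): the half-normal
process is removed; each covariate gets state-specific coefficients
(pre-parturition vs after-death) around a shared intercept, fit with the
same priors and sampler, and summarised as Pre/AD rows with AD-vs-Pre
overlap. It aborts below a configurable minimum of post-mortality rows
(default 200).

## Validation studies and problem sizes

`validation.parameter_recovery_study` (the evidence behind the quoted
tolerances): 20 replicates of a reduced scenario — 6 pregnant females,
one 150-day season starting day-of-year 32, a 128x128 10-m landscape,
covariates elevation (time-varying, truth `beta = 0.5`, `gamma = 1.0`,
`sigma = 20` d) and slope (constant, `beta = −0.5`), `step_sd_m = 740` so
candidate discs cover the landscape and coincide with the pooled
availability domain, 400 candidates/step, 10:1 availability at the known
generative radius, matched-likelihood ML plus 3 chains x 1,500 iterations
(400 burn-in). Median absolute errors observed (master seed 1): base
coefficients ~0.016, gamma ~0.06–0.07, sigma ~8% relative; 95% CrI
coverage 98.75% over 80 parameter-replicate checks; worst Rhat 1.04. The
full study runs in roughly six minutes on one CPU.

`validation.stepwise_selection_study`: 20 replicates, 4 females x 100
days, elevation truth |beta| = 1 vs annual cover truth beta = 0; the noise
covariate is dropped in ~95% and the strong covariate retained in 100% of
replicates.

`scripts/acceptance.py` reruns both studies from scratch plus the
availability bookkeeping (20,884 used -> 208,840 available), the doubled
return-time transformation of the published posterior-mean scales, and the
AICc spot value, writing everything to JSON.

## Numerical choices and degenerate inputs

* Bernoulli log-likelihood via `logaddexp` (stable at extreme logits);
  matched likelihood max-shifted per stratum.
* Quantiles are NumPy linear-interpolation quantiles.
* Zero-variance covariates, empty water lists, inverted relief ranges,
  degenerate step-length distributions, sub-minimum MCMC draw counts and
  stuck chains raise immediately with explicit messages.
* Seeds: every stochastic component takes a seed; composite stages spawn
  child seeds with `numpy.random.SeedSequence`, so one master seed fixes a
  whole run.

## Known limitations

* The pooled-Bernoulli `gamma` attenuation described above is a property
  of the reference protocol itself; conclusions about the *magnitude* of
  post-parturition shifts from that protocol are conservative.
* Euclidean (not cost) distance to water; classic (not localized) VRM.
* The movement model is a selection kernel, not a realistic correlated
  walk; availability radii estimated from its steps are wider than true
  displacement scales of real sheep.
* Published coefficient values from the original field study cannot be
  reproduced without its collar data; validation is entirely
  property-based.
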