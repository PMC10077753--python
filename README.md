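# reprorsf — reproductive-state-varying resource selection

`reprorsf` estimates how habitat selection by GPS-collared ungulate
females changes with reproductive state: selection coefficients shift
abruptly at parturition and relax back to baseline as the neonate grows.
It is written for movement ecologists analysing collar + vaginal-implant
datasets (the motivating system is desert bighorn sheep provisioning
lambs in rugged montane terrain), and it ships a synthetic
landscape-and-telemetry generator so every stage can be validated against
known truth.

## The model

A use-availability (RSF) logistic model in which each coefficient follows
a half-normal return process:

```
logit(p_ijk) = β₀ + Σₙ βₙ,ij · Xₙ,ijk

βₙ,ij = (1 − Lamb_ij) · βₙ_base
      + Lamb_ij · [ βₙ_base + γₙ · exp(−Part_ij² / (2σₙ²)) ]
```

`Lamb` flags a live dependent neonate, `Part` is days since parturition,
`γₙ` is the immediate post-parturition shift and `σₙ` (days) the
half-normal return scale — the effective return time is `2σₙ`. A
`literal_zero` decay mode, in which the whole coefficient decays to zero,
is also provided. Fitting is by maximum likelihood with AICc backward
elimination of uninformative terms, then Bayesian MCMC (adaptive
random-walk Metropolis, 3 chains, Gelman–Rubin diagnostics) on the top
model, with vague priors: Normal(0, var 10) on coefficients, Uniform(1, 60)
on each σ. A matched conditional-logit likelihood is available alongside
the pooled Bernoulli one; `docs/methods.md` explains when and why it is
the better-specified estimator.

## Layout

- `src/reprorsf/` — the library: `grids` (synthetic terrain: Horn slope,
  Sappington VRM, distance-to-water, correlated vegetation covers),
  `movement` (collar simulation with known selection parameters), `prep`
  (fix screening, reproductive labelling, 10:1 availability sampling),
  `model` (process model, likelihoods, ML, AICc stepwise), `bayes`
  (MCMC, Rhat, posterior summaries, return rates, trajectories, the
  post-mortality contrast model), `pipeline` (orchestration + manifests),
  `validation` (known-truth studies).
- `analysis/01…05` — numbered drivers running the pipeline in protocol
  order; outputs land under `results/`.
- `scripts/acceptance.py` — recomputes the headline validation numbers.

## Worked example

```
python analysis/01_simulate.py --seed 1
python analysis/02_prepare.py
python analysis/03_fit_selection_model.py
```

With the default reduced scenario (12 females, one 150-day season,
128×128 10-m landscape) this prints:

```
landscape: (128, 128) cells, 8 layers
females: 12 (7 neonate deaths)
fixes acquired: 10251 (scheduled 900 per animal)
fix-rate screen: 10251 -> 10251 (removed animals: [])
2-D removal:     10251 -> 9757
subsampling:     9757 -> 6826
availability radius: 242.0 m
dataset1: 5755 used + 57550 available rows
dataset2 (post-mortality): 1071 used rows
top model covariates: ('elevation', 'slope')
time-varying terms:   ('elevation',)
AICc of top model:    32717.2
worst Rhat:           1.020

coefficient summary (Table-1 shape):
    Parameter   Mean  Lower 95% CI  Upper 95% CI  Probability > 0  Probability < 0  Overlap with Pre
Pre elevation  0.978         0.919         1.038            100.0              0.0               NaN
 PP elevation  1.310         1.212         1.418            100.0              0.0               0.0
    Pre slope -0.500        -0.526        -0.475              0.0            100.0               NaN

return rates, raw and doubled (Table-2 shape):
Parameter   Mean  Lower 95% CI  Upper 95% CI  Adjusted mean  Adjusted lower 95% CI  Adjusted upper 95% CI
elevation 27.192        16.805        43.837         54.385                 33.609                 87.675
```

Reading the output: the screening chain reports how many fixes each
filter removed; every used fix is matched with exactly 10 available
points inside the pooled 2.58×SD step-length buffer (242 m here). The
coefficient summary gives each covariate's pre-parturition (`Pre`)
posterior and, for time-varying terms, the immediate post-parturition
(`PP`) posterior with its percent overlap with `Pre` — here selection for
high elevation jumps after parturition (PP distribution essentially
disjoint from Pre) and the doubled σ says it takes ≈54 days (95% CrI
34–88) to return to baseline. `04_fit_mortality_model.py` adds the
pre-parturition vs post-loss contrast, and `05_validation_studies.py`
reruns the known-truth recovery study.

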