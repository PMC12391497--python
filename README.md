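# bmimed

Nonlinear causal mediation of the BMI–survival association through
epigenetic age acceleration.

Both low and high body-mass index are associated with shorter survival in
older adults, and with faster biological ageing as measured by DNA-methylation
("epigenetic") clocks.  `bmimed` implements, as a reusable and fully tested
pipeline, the analysis that asks how much of the BMI–survival association
flows *through* epigenetic ageing: restricted-cubic-spline regressions of each
clock's age acceleration (EAA) on BMI, left-truncated Gompertz
proportional-hazards models of mortality on the age timescale, and a
counterfactual decomposition of the effect of a BMI contrast on mean survival
time into a direct and a mediated component, with bootstrap confidence
intervals.  Because the motivating cohort data (a population survey with
venous-blood DNA methylation) are registration-gated, the package ships a
synthetic-cohort generator with the same statistical structure and a
Monte-Carlo oracle for the true effects, so every stage is verifiable end to
end.

## The model

For subject *i* with baseline age `a_i`, BMI `b_i`, covariates `c_i`
(sex, ethnicity, education, smoking, metabolic health) and mediator `m_i`
(one clock's EAA, or DunedinPACE on its own scale):

* **Mediator model** — ordinary least squares,
  `m_i = α₀ + s(b_i)ᵀα_b + age/covariate terms + ε_i`,
  with `s(·)` a restricted cubic spline (4 knots at the 5/35/65/95%
  quantiles; linear beyond the boundary knots).
* **Outcome model** — Gompertz proportional hazards with *age* as the
  timescale and delayed entry at `a_i`:
  `h(t | x_i) = exp(log b + γ t + s(b_i)ᵀβ_b + β_m m_i + c_iᵀβ_c)`.
  The left-truncated, right-censored log likelihood is maximised by Newton
  iteration on the analytic gradient and Hessian; the Gompertz family is
  checked against exponential and Weibull alternatives by AIC.
* **Counterfactual effects** — with `m_i(e)` the mediator predicted at BMI
  level `e` and `Y_i(b, m)` the model-implied mean residual survival time
  from `a_i` (numerical integration of the conditional survival curve,
  truncated at 130 y), the average causal mediation effect and average
  direct effect for an exposed-vs-reference contrast `(e₁, e₀)` are

      ACME = ½ Σ_e mean_i [ Y_i(e, m_i(e₁)) − Y_i(e, m_i(e₀)) ]
      ADE  = ½ Σ_e mean_i [ Y_i(e₁, m_i(e)) − Y_i(e₀, m_i(e)) ]

  averaged over `e ∈ {e₁, e₀}`, so that `ADE + ACME` equals the total
  effect exactly.  Intervals are 95% percentile bootstrap (3000 subject
  resamples by default; spline knots frozen at full-sample placement).

Default contrasts are the published ones: low BMI 19 vs 27 kg/m² and high
BMI 35 vs 27 kg/m², the reference being the BMI of longest predicted
survival.

## Worked example

The numbered drivers under `analysis/` run the whole plan on the default
synthetic cohort (n = 3840, seed 20160301) and write their tables to
`results/`:

```sh
cd analysis
python 01_simulate_cohort.py   # raw subject table
python 02_prepare_cohort.py    # exclusions, EAA residuals, Table-1 analogue
python 03_survival_models.py   # AIC comparison, HRs per SD, LE-vs-BMI curve
python 04_mediator_models.py   # spline fits, BMI nadirs, mediator screen
python 05_mediation.py         # ADE/ACME with bootstrap CIs
```

`05_mediation.py` prints, for this cohort (GrimAge is the clock that truly
drives mortality in the generator; the others act as negative controls):

```
grimage       low : ADE -5.70 (-8.08,-3.30)  ACME -2.07 (-2.77,-1.51), 27% mediated
grimage       high: ADE -2.45 (-4.53,-0.43)  ACME -1.36 (-1.85,-0.99), 36% mediated
hannum        high: ADE -3.85 (-6.05,-1.85)  ACME +0.01 (-0.22,+0.25)
```

Read: moving a subject from BMI 27 to 35 kg/m² costs about 3.8 years of mean
survival time in total, of which 1.36 years (36%) is mediated by
GrimAge acceleration; the Hannum interval straddles zero because that clock
has no causal path to mortality in the generator.  `03_survival_models.py`
reports the Gompertz family first by AIC (Δ ≈ 231 over Weibull), the longest
predicted survival at BMI 27.5, and a GrimAge hazard ratio of 1.71 per SD
(95% CI 1.55–1.89).

The same pipeline runs on any schema-conformant CSV of real subjects, from
the shell:

```sh
bmimed simulate --n 3840 --seed 7 --out run/
bmimed prepare run/cohort_raw.csv --out run/
bmimed run config.yaml
```

## Layout

```
src/bmimed/      splines, cohort, design, gompertz, mediator, mediation,
                 simulate, pipeline, cli
analysis/        numbered narrative drivers (thin wrappers over the library)
results/         small tables the drivers write
tests/           pytest suite incl. acceptance criteria
docs/methods.md  modelling assumptions, parameter choices, limitations
```
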