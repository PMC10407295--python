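# crpbayes

Bayesian hierarchical and distributional Student-t regression of
C-reactive protein (CRP) on socioeconomic status, with a Gaussian-copula
synthetic survey generator and a pure-NumPy Hamiltonian Monte Carlo sampler.

## The problem

CRP is an acute-phase inflammation biomarker (mg/L); values above 3 mg/L
mark low-grade systemic inflammation and elevated cardiovascular risk.
Socioeconomic status (SES) — occupational class, education, equivalized
household income — is associated not only with *average* CRP but plausibly
also with its *spread* within social groups. `crpbayes` implements the two
models that make this question answerable:

**Model 1** (hierarchical, homoscedastic). For person *i* with log-CRP
*y\_i*:

```
y_i ~ StudentT(ν, μ_i, σ)
μ_i = β₀ + x_iᵀβ + u_edu[e_i] + u_occ[o_i]
```

with x the fixed effects (gender, house ownership, self-rated health,
smoking, plus z-scored sport activity, age, equivalized income and BMI) and
u the education / occupation group deviations, u ~ N(0, sd²) with
half-Cauchy(0, σ\_y) priors on the group SDs. The Student-t likelihood with
an Exponential(1/29) prior on ν − 1 makes the fit robust to the heavy
outliers typical of inflammation assays.

**Model 2** (distributional / location–scale). The residual scale gets its
own linear predictor,

```
ln σ_i = γ₀ + x_iᵀγ + v_edu[e_i] + v_occ[o_i]
```

so between-group differences in *within-group* CRP dispersion — the
within-group component of total health inequality — become estimable.

Both posteriors are sampled with four HMC chains of 2000 iterations
(first 1000 discarded as warmup/adaptation), using analytic gradients on
an unconstrained, non-centered parameterization.

The real analysis sample (a UK household health-assessment panel with
nurse-collected bloods) is access-restricted, so the package ships a
calibrated synthetic generator: covariates come from a Gaussian copula
matched to the survey's published means/SDs, category proportions and
correlation structure, and responses are simulated from either model. A
raw fixture reproduces the survey's missingness pattern (9896 records: 521
missing CRP, 283 without usable height/weight, 132 with another missing
covariate, leaving the 8960-person analytic sample).

## Worked example

```
crpbayes --mode synthetic --model 1 --n 1000 --chains 4 \
         --iter 1000 --warmup 500 --seed 42 --out-dir demo
```

generates 1000 synthetic survey records, fits Model 1 and writes summary,
contrast, diagnostic and report files. The run prints
`run complete: demo (8.6s)` and `demo/summary_model1.csv` begins
(values rounded to three decimals here):

```
parameter,mean,sd,q2.5,q50,q97.5
intercept,0.402,0.120,0.165,0.401,0.642
gender_female,0.170,0.063,0.048,0.170,0.290
house_ownership_rent,0.164,0.074,0.020,0.165,0.308
```

Read: at this sample size the posterior mean log-CRP of women exceeds
men's by 0.170 (95% credible interval 0.048–0.290) holding the other
covariates fixed — the generating value was 0.150. The manifest records
`max_rhat 1.0066` and `min_ess 595`, i.e. all four chains mixed; the run
aborts with a distinct exit code if any parameter's split R-hat exceeds
1.05. `contrasts_model1.csv` holds the per-category posterior contrasts
against the reference occupation/education with central 65% density
intervals, and `income_lines_model1.csv` 20 (intercept, slope) pairs drawn
from the posterior of the income effect.

The same entry points are available as a library:

```python
import crpbayes as cb

raw = cb.generate_raw_fixture(seed=0)        # 9896 rows, survey missingness
analytic, log = cb.prepare(raw)              # 8960-row analytic sample
design = cb.encode_design(analytic)
```

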