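# matage — age-by-maternal-age matrix population models

`matage` turns daily individual life-history records — one row per
individual per day, with survival status and offspring counts — into
age × maternal-age structured matrix population models, and runs the
demographic analyses built on them.  It was written for laboratory
life-table experiments on clonal rotifers (*Brachionus manjavacas*) in
which cohorts of known maternal age (3, 5, 7 or 9 days) are followed daily
under ad libitum (`AL`) or chronically restricted (`LF`, low food) rations,
but the machinery applies to any organism where an individual's fixed
maternal age and its current age jointly drive survival and fertility
(maternal effect senescence, a.k.a. the Lansing effect).

## The model

The population state is a vector **n**<sub>t</sub> over classes
(maternal age *i*, age *j*), *i*, *j* ∈ 1..19, maternal ages nested within
age classes.  One day of dynamics is

> **n**<sub>t+1</sub> = (**U** + **F**) **n**<sub>t</sub> = **A** **n**<sub>t</sub>

where **U** holds survival probabilities *p*<sub>ij</sub> on diagonal
blocks of its block subdiagonal (age advances, maternal age never changes)
and **F** holds fertility coefficients *f*<sub>ij</sub> in its first block
row — the offspring of an age-*j* mother are newborns *of maternal age j*.
Because reproduction is continuous within each 1-day census interval, the
vital rates use a birth-flow discretisation:

> *p*<sub>ij</sub> = [*l*(*i*,*j*) + *l*(*i*,*j*+1)] / [*l*(*i*,*j*−1) + *l*(*i*,*j*)],
> *f*<sub>ij</sub> = [*m*(*i*,*j*) + *p*<sub>ij</sub> *m*(*i*,*j*+1)] / 2

with survivorship *l* and daily fertility *m* estimated nonparametrically:
Kaplan–Meier survivorship and mean daily offspring per cohort, linear
interpolation of curves at unobserved maternal ages 4/6/8, and geometric
extrapolation (cumulative-fertility ratio *r*, survivorship multiplier *k*)
to maternal ages 10–19.  From **A** the package computes the population
growth rate λ (dominant eigenvalue), stable structure **w**, reproductive
values **v**, and the net reproductive rate
R₀ = ρ(**F**(**I** − **U**)<sup>−1</sup>).  On top of that sit:

* **stationary scenarios** — divide **F** by the ad libitum R₀ (low
  fertility), or multiply **U** by the constant *c* solving λ = 1 (low
  survival), applying the same constant to both treatments;
* **fixed-design LTRE** — λ<sub>LF</sub> − λ<sub>AL</sub> ≈ Σ (Δ*a*<sub>xy</sub>) ∂λ/∂*a*<sub>xy</sub>
  evaluated at the mean matrix, split into fertility and survival
  contributions on the (maternal age, age) grid;
* **permutation tests** — individuals reshuffled between treatments within
  their maternal-age cohort, the whole pipeline re-run per shuffle, giving
  null distributions for |Δλ|, |ΔR₀| and ‖Δ**w**‖₁;
* **a synthetic-data generator** with closed-form ground-truth surfaces
  (Gompertz mortality with a proportional maternal-age effect, Poisson
  daily fertility with a gamma-kernel schedule) for validation.

## Worked example

```python
import matage as mg
from matage import scenarios as sc

table = mg.generate(mg.SyntheticParams(), seed=1)   # 2 x 4 x 70 design
models = {}
for treatment in ("AL", "LF"):
    surfaces = mg.build_rate_surfaces(table, treatment)
    models[treatment] = mg.assemble(surfaces)
    summary = mg.eigen_summary(models[treatment])
    print(f"{treatment}: lambda = {summary.lambda_:.4f}, R0 = {summary.r0:.4f}")

c = sc.solve_survival_multiplier(models["AL"], target_lambda=1.0)
print(f"survival multiplier for a stationary AL population: {c:.4f}")

ltre = mg.ltre_contributions(models["LF"], models["AL"])
print(f"delta lambda = {ltre.delta_lambda:.4f}; "
      f"fertility contributions = {ltre.fertility_sum:.4f}, "
      f"survival contributions = {ltre.survival_sum:.4f}")

perm = mg.permutation_test(table, n_permutations=999, seed=1)
print("permutation p-values:", perm.p_values)
```

prints

```
AL: lambda = 1.9527, R0 = 19.6065
LF: lambda = 1.8780, R0 = 21.4593
survival multiplier for a stationary AL population: 0.3886
delta lambda = -0.0747; fertility contributions = -0.0869, survival contributions = 0.0119
permutation p-values: {'lambda': '< 0.001001', 'r0': 0.002002002002002002, 'structure': '< 0.001001'}
```

Reading: the ad libitum population nearly doubles daily (λ ≈ 1.95) while
caloric restriction lowers λ by ≈ 0.07 — a difference no shuffle of
individuals between treatments reproduced (p < 1/999).  A stationary
population would need survival cut to ≈ 39% of laboratory levels.  The
LTRE attributes most of the λ deficit to fertility differences at young
ages, partly offset by the survival benefit of restriction.

The same pipeline runs from the shell:

```sh
matage simulate --seed 1 --out table.csv
matage validate table.csv
matage analyze table.csv --treatment AL
matage scenarios table.csv --mode low_survival
matage ltre table.csv --scenario laboratory
matage permtest table.csv --n-perm 999 --seed 1
matage run --config study.yaml        # everything, into a run directory
```

Real data are supplied as a long-format CSV with columns
`individual_id, treatment, maternal_age, age_day, status, offspring`
(`status` ∈ alive/dead/censored; see `matage.data_io`).

## Layout

| module | contents |
| --- | --- |
| `matage.data_io` | CSV reading/writing, validation, cohort census |
| `matage.rate_surfaces` | KM survivorship, fertility curves, interpolation/extrapolation to the 19×19 grid |
| `matage.matrix_model` | block-matrix assembly, λ/w/v/R₀, projection |
| `matage.scenarios` | stationary rescalings, single-maternal-age populations |
| `matage.ltre` | sensitivities and LTRE contribution grids |
| `matage.permutation` | individual-level treatment-shuffle tests |
| `matage.synthetic_data` | generative model with known ground truth |
| `matage.workflow` | one-config end-to-end runs with a manifest |

See `docs/methods.md` for the estimation details, numerical choices and
known limitations.
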