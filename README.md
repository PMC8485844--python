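# ed50-mcid

Baseline-severity-dependent minimal clinically important differences (MCID)
for bounded symptom questionnaires — the PHQ-9 (depression, 0–27) and GAD-7
(anxiety, 0–21) — estimated by the **effective dose 50 (ED50)** method.

## The problem

How much does a depression or anxiety score have to improve before the
patient actually feels better?  A single population-average MCID hides a
strong *baseline dependency*: patients starting at severe symptom levels
need much larger changes than patients starting mild.  This package
calibrates questionnaire change scores against a patient-reported anchor —
the Global Rating of Change (GRC, "do you feel better / the same / worse
since last seen?") — and reads the MCID off a fitted probability surface at
every level of baseline severity.

## The model

Each follow-up interval contributes one observation with a *rolling
baseline*: at visit *t* the change is `x_(t-1) − x_t`, so positive changes
are improvements.  The dichotomized anchor (better vs not better) is
modelled with a logistic generalized additive mixed model

```
logit P(better) = f(change, baseline) + u_patient,   u_patient ~ N(0, σ_u²)
```

where `f` is a tensor-product smooth built from an *integrated-spline*
margin in the change direction.  Constraining its tensor coefficients to be
non-negative makes the surface monotone: more improvement never lowers the
modelled probability of feeling better.  Random intercepts absorb the
correlation between a patient's repeated intervals and are integrated out
by a Laplace approximation; smoothing parameters and σ_u are selected by
restricted maximum likelihood (REML) on that approximate marginal
likelihood.

The MCID at baseline *b* is the **ED50**: the smallest change `c ∈ [0, b]`
with `P(better | c, b) ≥ 0.5`, floored at zero change (a deterioration is
never an improvement) and flagged `N.A.` where even the largest feasible
improvement cannot reach the probability.  ED25 and ED75 bracket it as
interval estimates, and the ED50 is also expressed as a percent of
baseline.  The classical comparator — the crude and standardized mean
difference between patients feeling *slightly better* and *about the
same*, `SMD = Δmean / √((s₁² + s₂²)/2)` — is included for reference.

Because the individual-level data of the source trials (PANDA and CoBalT)
are not publicly deposited, the package ships a synthetic-trial generator
that emulates their pooled design — two studies with different
baseline-severity distributions, follow-up schedules, and GRC granularities
(5-level vs 3-level) — from a logistic-linear truth with a closed-form ED
oracle, so every stage of the pipeline is testable end to end.

## Worked example

```python
from ed50mcid import (
    PHQ9, compute_changes, anchor_validity, fit_gamm,
    build_ed_table, compute_metrics, default_config, generate_trial,
)
from ed50mcid.synthetic_data import grc_mappings

config = default_config("PHQ9")          # two-study pooled trial, 800 patients
visits, truth = generate_trial(config)
records = compute_changes(visits, PHQ9, grc_mappings(config))

print(anchor_validity(records).round({"rho": 2}).to_string(index=False))
surface = fit_gamm(records)              # monotone logistic GAMM, REML
table = build_ed_table(surface, PHQ9, records)
```

The anchor-validity step prints Spearman correlations per study and
interval (negative because "a lot better" is coded as the lowest rank; all
exceed the |rho| ≥ 0.30 adequacy gate):

```
study_id  interval_index   n   rho  passes
  COBALT               1 334 -0.48    True
  COBALT               2 334 -0.41    True
  COBALT               3 334 -0.36    True
  COBALT               4 334 -0.31    True
   PANDA               1 466 -0.58    True
   PANDA               2 466 -0.43    True
   PANDA               3 466 -0.32    True
```

and the ED table shows the baseline dependency directly — no change needed
at minimal severity, about 12 points at the top of the scale, with ED75
unattainable (`N.A.`) at baseline 1 where only one point of improvement is
possible:

```
              band   ED25   ED50  ED50_percent   ED75
baseline
1          Minimal   0.00   0.00          0.00   N.A.
5             Mild   0.00   1.15         23.07   3.88
10        Moderate   1.58   4.14         41.39   6.71
15          Severe   4.65   7.03         46.88   9.39
20          Severe   7.01   9.17         45.87  11.29
27          Severe  10.04  11.74         43.46  13.37

sample averages: ED25 3.54, ED50 5.58 (38.1%), ED75 8.22
```

Evaluating the ED50 rule against the anchor on the same records gives
`sensitivity 0.59, specificity 0.91, disagreement 17.2%`.

The same pipeline is available from the shell:

```sh
ed50-mcid simulate --scale PHQ9 --seed 20210401 --out visits.csv
ed50-mcid run-all --input visits.csv --out results/
```

`run-all` writes the observation table, anchor-validity table, serialized
surface (JSON), ED table, classification metrics, group change summaries,
and the SMD comparator table, plus a full-precision `results.json` and a
run log.  Real study data can be analysed the same way: the input is a
long-format CSV with columns `patient_id, study_id, visit_index, scale,
score, grc` (GRC empty at the first visit), with per-study GRC label
mappings configurable in YAML.

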