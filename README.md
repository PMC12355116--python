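# gabadose

Pharmacoepidemiology of high-dose gabapentinoid (pregabalin / gabapentin)
use from pharmacy-claims dispensing data.

National claims databases record *when* a drug was dispensed and *how much*,
but not the prescribed daily dose. This package implements the standard
claims-based workflow for estimating how often patients end up on doses
above the maximum recommended dose — a proxy for potential abuse and misuse
— and which baseline factors are associated with it:

1. **New-user cohorts** — patients with ≥3 dispensings of the index drug
   within 12 months, a 12-month drug-free washout, age ≥18, known
   demographics and continuous enrolment, with a full attrition audit trail.
2. **Treatment episodes** — maximal runs of dispensings separated by at most
   a gap threshold (35 days = 4 weeks' maximum supply + 1 week grace;
   sensitivity 42/56). The average daily dose over an episode is total mg
   dispensed divided by episode duration, standardised in Defined Daily
   Doses (DDD; pregabalin 300 mg, gabapentin 1800 mg). *High-dose* means an
   average daily dose strictly above 2 DDD (600 / 3600 mg per day).
3. **Survival analysis** — time from cohort entry to the midpoint of the
   first high-dose episode, censored at death, loss to follow-up or 24
   months; Kaplan–Meier cumulative incidence F(t) = 1 − S(t), log-rank
   comparison between cohorts, and person-year incidence rates with 95% CIs.
4. **Cox models** of associated factors with restricted cubic splines
   (df = 5) for continuous covariates, Efron ties, robust (sandwich)
   variance, Grambsch–Therneau proportionality tests and smoothed
   time-varying coefficients β(t).
5. **Initiation trends** — monthly new users per 100,000 inhabitants,
   decomposed into trend + seasonal + remainder with STL.

Because real claims extracts cannot be shared, the package bundles a
**synthetic claims generator** (`gabadose.simulate`) whose event process is
an exponential proportional-hazards model with configurable hazard ratios:
every downstream stage is testable end-to-end against known ground truth,
including full-chain parameter recovery.

## Worked example

```python
import gabadose as g

# 1. simulate a claims extract with known ground truth
g.simulate_dataset(g.SimulationConfig(n_patients=20_000, seed=3), "simdata")

# 2. run the full pipeline on it
cfg = g.PipelineConfig(
    patients_path="simdata/patients.csv",
    dispensings_path="simdata/dispensings.csv",
    enrolment_path="simdata/enrolment.csv",
    deaths_path="simdata/deaths.csv",
    population_path="simdata/population.csv",
    output_dir="out",
)
results = g.run_pipeline(cfg)
for drug in ("pregabalin", "gabapentin"):
    inc = results[f"{drug}/incidence"][35]
    print(drug, round(inc["rate_per_1000py"], 1),
          [round(x, 1) for x in (inc["ci95_low"], inc["ci95_high"])])
```

prints

```
pregabalin 26.1 [24.0, 28.1]
gabapentin 9.7 [7.4, 11.9]
```

— the incidence of high-dose use per 1000 person-years in each simulated
cohort with natural-scale Wald CIs. The default generator is calibrated so
cohort structure (median age 64, ~58% women, median 4 treatment episodes of
~50 days) and event rates sit near the values reported for the French
2017–2021 cohorts. `out/` additionally holds, per drug: `cohort.csv`,
`attrition.csv`, `episodes.csv`, `tte.csv`, `km.csv`, `factors.csv` (hazard
ratios with robust CIs), `spline_curves.csv`, `trends.csv` and a run
manifest.

The same stages are available on the command line:

```bash
gabadose simulate --n-patients 20000 --seed 3 --out simdata
gabadose run-all --data-dir simdata --out out
gabadose cohort --data-dir simdata --drug pregabalin   # attrition trail
```

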