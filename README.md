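# vilpa

**Wrist-accelerometer VILPA extraction and mortality dose–response
modelling.**

VILPA — vigorous intermittent lifestyle physical activity — is brief
(up to 1–2 min) vigorous-intensity movement embedded in everyday life:
bursts of very fast walking, stair climbing, carrying heavy shopping.
Wearable devices can capture these micro-patterns, and in epidemiological
cohorts even a few minutes per day are associated with substantially lower
all-cause, cardiovascular and cancer mortality. This package implements
the full analytic pathway from classified 10-second accelerometer epochs
to those dose–response estimates, for biostatisticians and physical
activity epidemiologists who want a tested, reusable implementation:

* **Bout engine** — intensity assignment (walking/running: <100 mg light,
  ≥100 mg moderate, ≥400 mg vigorous), maximal-run bout detection with
  ≤1-min / ≤2-min / long-VPA (>12 windows) categories, rolling-sum length
  standardization (e.g. raw bouts of 20+30+20+40+10 s → 1.83 one-minute
  analytic bouts), wear-validity rules (>16 h/day; ≥3 valid days incl. a
  weekend day), per-valid-day averaging, 97.5th-percentile capping.
* **Survival models** — statsmodels-style model/results classes:
  `CoxDoseResponse` (all-cause) and `FineGrayDoseResponse`
  (subdistribution hazards for competing causes), with the exposure in a
  restricted cubic spline (knots at the 10th/50th/90th percentiles),
  2-year landmark and prevalent-disease exclusions, Wald test for
  departure from linearity and Schoenfeld-residual proportional-hazards
  diagnostics. The fitted log hazard is
  `log h(t|x,z) = log h0(t) + f(x)'β + z'γ` with `f` the 3-knot restricted
  cubic spline and exposure 0 as the referent.
* **Dose–response outputs** — `HR(x) = exp(f(x)'β − f(0)'β)` curves with
  delta-method 95% bands, the minimal dose (ED50: the exposure giving 50%
  of the optimal risk reduction), HRs at the median/maximum exposure, and
  E-values (`E = RR + √(RR(RR−1))`, `RR = 1/HR` for protective estimates)
  for unmeasured-confounding sensitivity.
* **Synthetic cohorts** — a seeded generator for epoch series (semi-Markov
  day structure with planted vigorous runs and a ground-truth log),
  covariates and competing-risks survival, so the entire pipeline is
  testable without access-controlled cohort data.

## Worked example

```python
import numpy as np
from vilpa import CoxDoseResponse, evalue, minimal_dose, hr_at
from vilpa.simulate import simulate_analysis_cohort

# 10,000 participants, true protective effect -0.08 log-HR per min/day
df = simulate_analysis_cohort(10_000, seed=7, beta=-0.08, baseline_hazard=0.012)

res = CoxDoseResponse(df, "exposure").fit()
print(res.summary().round(3).head(2))
print("knots:", tuple(round(k, 2) for k in res.spline.knots))
print("nonlinearity p:", round(res.wald_nonlinearity().p_value, 3))

curve = res.curve()
md = minimal_dose(curve)
x_med = float(np.median(df.loc[df.exposure > 0, "exposure"]))
hr_med, ci_med = hr_at(curve, x_med)
print(f"ED50: {md.ed50_exposure:.2f} min/day -> HR {md.hr_at_ed50:.2f} "
      f"({md.ci[0]:.2f}, {md.ci[1]:.2f})")
print(f"median exposure {x_med:.2f} min/day -> HR {hr_med:.2f} "
      f"({ci_med[0]:.2f}, {ci_med[1]:.2f})")
ev = evalue(hr_med, ci_med[1])
print(f"E-value at median: {ev.rounded()[0]:.2f} (CI limit {ev.rounded()[1]:.2f})")
```

prints (950 deaths among 10,000 over the 6.9-year horizon):

```
                coef     se      z      p     hr  hr_lower_95  hr_upper_95
covariate
exposure_lin  -0.047  0.028 -1.679  0.093  0.954        0.902        1.008
exposure_rcs1 -0.013  0.037 -0.356  0.722  0.987        0.918        1.061
knots: (0.0, 3.52, 8.95)
nonlinearity p: 0.722
ED50: 8.95 min/day -> HR 0.61 (0.50, 0.73)
median exposure 4.00 min/day -> HR 0.82 (0.69, 0.97)
E-value at median: 1.74 (CI limit 1.21)
```

Read: the adjusted dose–response is compatible with linearity
(nonlinearity p = 0.72); a median 4 min/day of VILPA corresponds to an
18% lower all-cause mortality hazard, and an unmeasured confounder would
need risk-ratio associations of 1.74 with both exposure and outcome to
explain that estimate away.

The same analysis runs end-to-end from epoch files at the shell:

```sh
vilpa simulate --n 200 --seed 1 --out-dir cohort/
vilpa run --epochs cohort/epochs.csv.gz --covariates cohort/covariates.csv \
          --outcomes cohort/outcomes.csv --out-dir results/ \
          --outcome all_cause --exposure duration --bout-length 1
vilpa evalue --hr 0.52 --ci-limit 0.72
```

`run` writes `report.json` (sample-flow counts at every exclusion stage,
knots, coefficients, diagnostics, ED50, HRs at median/max, E-values) and
`curve.csv`; reruns on the same inputs are byte-identical.

See `docs/methods.md` for the model details, generator assumptions and
numerical conventions.

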