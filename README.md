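# gadopk

Quantitative liver-function biomarkers from gadoxetate-enhanced DCE-MRI,
and a translational framework for predicting drug-induced liver injury
(DILI) risk in individual patients from rat dose-response experiments.

Gadoxetate (Gd-EOB-DTPA) is a liver-specific MRI contrast agent taken up
by hepatocytes through OATP1B1/B3 transporters (rate `k_i`, s⁻¹) and
excreted into bile through MRP2 (rate `k_ef`, s⁻¹). Because many
hepatotoxic drugs inhibit exactly these transporters, the fitted rates are
direct, mechanistic liver-function biomarkers. `gadopk` is aimed at
pharmacometricians and imaging scientists who need to

* simulate and fit compartmental models of gadoxetate kinetics
  (**Patlak**, dual-input **perfusion**, and a closed **whole-body**
  model) to concentration time series from liver, spleen and blood;
* quantify per-patient parameter uncertainty by **profile likelihood**
  (95% CI where the re-optimized χ² exceeds the optimum + χ²₀.₉₅(1));
* estimate a **Hill dose-response** of drug-inhibited transport rates over
  a rat cohort with a nonlinear mixed-effects (SAEM) fit,

  k<sub>x,j</sub> = min<sub>x</sub> + (max<sub>x</sub> − min<sub>x</sub>) / (1 + (IC50<sub>x</sub>/dose<sub>j</sub>)^Hill<sub>x</sub>) + p<sub>x,j</sub>,  p<sub>x,j</sub> ~ N(0, ω<sub>x</sub>²);

* **translate** the rat curve to an individual patient
  (max<sub>human</sub> = k<sub>human</sub>; min<sub>human</sub> =
  max<sub>human</sub>·min<sub>rat</sub>/max<sub>rat</sub>; IC50 and Hill carried over) and
  compute the **maximal allowed dose** before predicted liver function
  drops below a normal-range limit, versus the drug's minimal required
  dose.

Since the underlying patient and rat datasets are not public, the package
ships a first-class synthetic-data module that emulates both protocols
(rat: one sample/min for 60 min, drug doses 0–2000 mg/kg; human:
breath-hold sampling to 30 min) with known ground truth, so every stage is
testable end to end.

## Worked example

```python
from gadopk import (RatCohortSpec, generate_rat_cohort, nlme_fit, NLMEConfig,
                    PatientBaseline, DosePlanningConfig, plan_dose)

cohort, truth = generate_rat_cohort(RatCohortSpec(seed=1))   # 30 rats
fit = nlme_fit(cohort, config=NLMEConfig(seed=1))
print(fit.params["k_i"])
# DoseResponseParams(min_x=1.35e-03, max_x=2.59e-02, IC50_x=38.7,
#                    Hill_x=-5.09, omega_x=1.26e-03)

res = plan_dose(PatientBaseline("P2", k_i_human=2.5e-3), fit.params["k_i"],
                DosePlanningConfig(normal_lower_limit=1.15e-3,
                                   minimal_required_dose=28.0))
print(res.maximal_allowed_dose, res.decision)
# 36.0 mg/kg, 'ok_to_use'
```

The fitted Hill curve says this drug halves hepatic uptake near 39 mg/kg
(one cohort realization of a true IC50 of 33.7) with a steep negative Hill
coefficient; for a patient whose drug-free uptake rate is 2.5×10⁻³ s⁻¹ the
predicted rate stays above the chosen normal-function limit up to ~36
mg/kg, which exceeds the 28 mg/kg needed for efficacy, so the drug is
usable for that patient. Every translation output carries a disclaimer:
the rat dose-response is assumed to hold in humans, which is an
approximation by design.

The `examples/` directory holds one short script per capability
(simulation, fitting + profiling, rat dose-response, human translation); a
thin CLI (`gadopk generate|fit|profile|doseresponse|translate|pipeline`)
wraps the same functions for shell use.

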