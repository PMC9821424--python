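# Methods

## Kinetic models

All three models describe the tissue concentration of gadoxetate (mM) as
linear, time-invariant compartmental systems; all rates are s⁻¹ and all
times are seconds internally (minutes are converted at the I/O boundary).

**Patlak.** The liver extracellular space is assumed to equilibrate
instantaneously with the input (blood or spleen-surrogate) concentration
C_in:

    C_liver(t) = v_ES · C_in(t) + C_H(t),
    dC_H/dt    = k_i · C_in(t) − k_ef · C_H,    C_H(0) = 0.

`v_ES` (extracellular volume fraction, default 0.23) is a fitted parameter
bounded to [0, 1]: profiling `k_i` must marginalize over it. C_in is
interpolated piecewise-linearly between samples — the sparse breath-hold
protocol makes higher-order interpolation unstable.

**Perfusion.** A dual-input two-compartment uptake model with explicit
extracellular transit and biliary efflux. Input is
f_a·C_a + (1−f_a)·C_pv, or a single (spleen-surrogate) curve:

    v_E dC_E/dt = F_p (C_in − C_E) − k_i C_E,
    v_H dC_H/dt = k_i C_E − k_ef v_H C_H,        v_H = 1 − v_E,
    C_liver     = v_E C_E + v_H C_H.

The hepatocyte influx is written as k_i·C_E per unit liver volume (an
uptake clearance per tissue volume). This puts k_i on the same scale in
every model, so that as F_p → ∞ the perfusion model reduces *exactly* to
Patlak with the same k_i, k_ef and v_ES = v_E — the property the package
verifies numerically — and fitted uptake rates are directly comparable
across models. Transport back to blood (MRP3/4) is not included in the
perfusion variant.

**Whole-body.** A closed system of amounts (mmol per kg body weight) in
plasma, a whole-body extravascular-extracellular pool (EES), hepatocytes,
and spleen interstitium, with a constant-rate injection (default 10 s —
a bolus whose exact duration is a free design choice), biliary (k_ef) and
renal (k_renal) elimination tracked as cumulative bile/urine states. The
liver extracellular space is kept in instantaneous equilibrium with plasma
(the Patlak assumption) to keep the system identifiable at the protocols'
sampling density; the spleen interstitium exchanges directly with plasma.
k_back (hepatocyte → blood) exists but defaults to 0. Two structural
volumes, `v_liver` and `v_spleen` (L tissue per kg body), convert between
organ concentrations and whole-body amounts; with them the hepatocyte
influx is again k_i·C_p per liver volume, Patlak-commensurate.
Observables: C_liver = v_ES_liver·C_p + v_H·C_H and
C_spleen = v_p_spleen·C_p + v_IS_spleen·C_IS.

The spleen observable is calibrated as a blood-pool surrogate
(v_p_spleen = 0.9, small interstitial term): spleen-input and blood-input
fits of the same data then give uptake rates on a common scale, which is
what the measured (normalized, relaxivity-converted) spleen curves provide
in practice.

**Integration.** All systems are advanced exactly: the Patlak state by the
closed-form first-order step for a linear-in-time input, the perfusion and
whole-body states by matrix exponentials per interval (the whole-body
matrix is constant, so exponentials are cached per step size). There is no
solver truncation error; mass conservation of the whole-body model holds
to machine precision.

**ΔR1 → concentration.** C = ΔR1 / r1 with r1 = 6.9 s⁻¹mM⁻¹ (blood and
spleen) and 10.7 s⁻¹mM⁻¹ (liver) at 1.5 T, and 5.9 s⁻¹mM⁻¹ (liver and
spleen) at 4.7 T. Blood at 4.7 T is undefined and rejected.

## Fitting and identifiability

The cost is χ² = Σ((y−ŷ)/σ)² over the fitted tissues (liver for Patlak and
perfusion; liver + spleen for whole-body). Optimization runs in log₁₀
parameter space with `scipy.optimize.least_squares` (TRF, bounds), with
log-uniform multistarts drawn from a seeded generator — results are
deterministic given the seed. Allowed ranges: hepatic rates 10⁻⁸–1 s⁻¹
(Patlak, perfusion) and 10⁻⁵–1 s⁻¹ (whole-body); F_p 10⁻⁴–10 s⁻¹; volume
fractions 10⁻³–1.

Free parameters: Patlak (k_i, k_ef, v_ES); perfusion (F_p, k_i, k_ef,
v_E); whole-body (k_i, k_ef, all four exchange rates, k_renal, v_p,
v_EES). The whole-body fit deliberately frees the body-pool volumes and
exchange rates: tissue volumes are not known a priori, and this
complexity is exactly what degrades the identifiability of its hepatic
rates relative to the simpler models.

Goodness of fit: pass iff χ² ≤ χ²-quantile(0.95, n_obs). The degrees of
freedom are the observation count (not n_obs − n_free), the convention
used in the source analyses; a corrected dof can be passed explicitly.
With noise on the *input* curve as well as the fitted data, the χ² is
over-dispersed (input noise propagates through the convolution), so the
95% calibration holds only when the input is treated as known; the
calibration tests are constructed that way.

Profile likelihood: the profiled parameter is stepped multiplicatively
(initial factor 1.1) away from the optimum, re-optimizing all other
parameters warm-started from the neighbouring step. The step doubles in
log scale while the cost climbs by less than 10% of the cutoff gap and
halves when the cutoff (optimal cost + χ²₀.₉₅(1) = 3.84) is overshot,
until the relative step is below 10⁻³; the CI bound is interpolated
linearly across the cutoff. Reaching the allowed parameter limit or the
step budget leaves that side open-ended (the reported bound is then the
allowed limit itself, flagged `lower_open`/`upper_open`). Rates span
decades, hence the multiplicative stepping.

## Dose-response mixed-effects model

Per-rat rates follow the Hill inhibition curve plus an additive individual
deviation p_x,j ~ N(0, ω_x²), independent between k_i and k_ef (scalar
random effect per parameter, no covariance). The curve is evaluated as
min + (max−min)/(1 + (dose/IC50)^(−Hill)) so that dose = 0 is exact (max
for Hill < 0, min for Hill > 0).

* **Two-stage fit** (also the initializer and independent cross-check):
  per-rat kinetic fits, then least squares of the Hill curve to the
  estimated rates on the log scale — rates span ~1.5 decades and the
  between-rat scatter is approximately proportional, so log-residuals are
  closer to homoscedastic. ω is the linear-scale residual SD.
* **SAEM**: the E-step samples each rat's deviations by random-walk
  Metropolis against exp(−χ²_j/2)·N(0, ω²) (two sweeps per iteration,
  proposal SD 0.3 ω, proposals making the rate non-positive rejected); the
  M-step refits the Hill curve to stochastically averaged individual rates
  and updates ω from averaged squared deviations. Gain is 1 for 300
  burn-in iterations, then 1/k for 200 more. Each rat's v_ES is fixed at
  its stage-1 estimate — the random effects act on the transport rates
  only. Deterministic given the seed.

Diagnostics report the per-rat deviations with dose labels, a sign test
that they vary evenly around zero, and a Spearman test for residual dose
correlation (which would indicate the fixed-effect curve missed part of
the dose dependence).

## Translation and dose planning

max_human = k_human (the patient's own drug-free rate), min_human =
max_human·min_rat/max_rat; IC50 and Hill are carried over from the rat
fit. The maximal allowed dose inverts the Hill curve in closed form at the
normal-function lower limit L,

    D = IC50 · ((max_h − L)/(L − min_h))^(−1/Hill),

with sentinels ∞ (L ≤ min_h: the limit is never crossed) and 0
(L ≥ max_h: already below normal). A drug is usable iff the minimal
required dose is strictly below D. The normal-range limit itself is a
required config input — it comes from a reference healthy cohort and is
not computed here. Every translation output embeds a fixed disclaimer
that the rat-to-human identity of the dose-response is an assumption.

## Synthetic data

The generators emulate the two study protocols: rats sampled every 60 s
for 3600 s at drug doses {0, 20, 50, 200, 2000} mg/kg with 6 rats per
group (30 rats); humans at {0, 20 s, 1, 3, 5, 8, 10, 13, 15, 18, 20, 23,
25, 28, 30} min. Ground-truth fixed effects default to the published rat
values (k_i: max 3.2×10⁻², min 1.4×10⁻³ s⁻¹, IC50 33.7 mg/kg, Hill −3.9;
k_ef: 3.5×10⁻³, 6.1×10⁻⁵, 32.4, −3.9). Defaults chosen where the sources
give none: between-rat SD 10% of the dose-predicted rate (the published
deviation scatter is not printed numerically), measurement noise 5% of
the curve peak (additive Gaussian on concentrations, constant σ per
curve, reported truthfully in the sigma column), human baseline k_i
log-normal around 2×10⁻³ s⁻¹ (the reported human range is 0–4×10⁻³),
gadoxetate dose 25 µmol/kg, 10 s infusion.

Each rat's input is its own whole-body spleen curve (so input and liver
data are mutually consistent and dose-dependent); the liver curve is the
Patlak response to the *noise-free* spleen input, so recovery targets
carry no model-mismatch error. Biology and noise use independent RNG
streams, so noise settings never perturb the parameter draws.
`input_noise_cv` decouples input noise from observation noise (0 gives
the correctly specified setting used for calibration checks).

What the generator does **not** emulate: Rician signal noise (noise is
added post-conversion), breathing/registration artefacts, flow artefacts
in vascular ROIs, inter-protocol relaxivity error, or any real drug's
pharmacokinetics. Passing recovery tests therefore demonstrates the
estimators are correct under the stated statistical model, not that real
data meet that model.

## Problem sizes and numerical choices

The shipped studies use the design sizes of the emulated experiments: 30
rats per cohort, 10 cohort realizations for the recovery study (5 in the
acceptance script, reporting medians), 10 synthetic patients for the
model-comparison profile study, 200 replicates for χ² calibration.
Degenerate inputs are rejected with validation errors (non-monotone
times, non-positive sigmas, doses < 0, inputs not covering the evaluation
window, both-or-neither perfusion inputs). Ties in the dosing decision go
to "need another drug" (strict inequality). A tiny σ floor (10⁻⁶ of the
peak) keeps χ² defined on noiseless synthetic curves.

## Known limitations

* The whole-body topology is one consistent reading of the schematic
  model (spleen interstitium exchanging directly with plasma); other
  routings would change the fitted exchange rates but not the hepatic
  observables' structure.
* SAEM assumes a constant ω per parameter while the generator's spread is
  proportional to the dose-predicted rate, a deliberate mild
  misspecification; recovery tolerances absorb it.
* The χ² test is anti-conservative on real data where the input curve is
  itself noisy (see above).
* Translation inherits every caveat of the rat-to-human assumption; the
  package surfaces this as a mandatory disclaimer rather than attempting
  to correct for it.
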