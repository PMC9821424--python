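"""Synthetic rat-cohort and human-subject generators.

The study's raw data (35 patients, 30 rats) are not deposited; these
generators emulate their statistical structure so that every downstream
stage (per-subject fitting, profiling, NLME dose-response, translation) can
be exercised and scored against a known ground truth.

Rat protocol: one sample per minute for 60 minutes; drug doses 0, 20, 50,
200 and 2000 mg/kg with 6 rats each (30 rats).  Human protocol: breath-hold
sampling at 0, 20 s, 1 min, then every 2-3 minutes (3, 5, 8, 10, ...) up to
30 minutes.  Inputs (spleen surrogate and blood) come from the whole-body
simulator so input and liver data are mutually consistent; liver curves are
generated from the Patlak model driven by the noise-free spleen curve, so
recovery targets are free of model-mismatch error.  Measurement noise is
additive Gaussian with SD = noise_cv x curve peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .data import SubjectDataset, TimeSeries, ValidationError
from .doseresponse import DoseResponseParams, evaluate_dose_response
from .models import PatlakParams, WholeBodyParams, simulate_patlak, simulate_wholebody

__all__ = [
    "TABLE_1A_TRUTH",
    "RAT_WHOLEBODY_DEFAULTS",
    "HUMAN_WHOLEBODY_DEFAULTS",
    "RatCohortSpec",
    "HumanProtocolSpec",
    "generate_input_function",
    "generate_rat_cohort",
    "generate_human_subject",
]

#: Reported rat dose-response parameters (fixed effects), used as the
#: default ground truth for cohort generation and recovery scoring.
TABLE_1A_TRUTH: dict[str, DoseResponseParams] = {
    "k_i": DoseResponseParams(min_x=1.4e-3, max_x=3.2e-2, IC50_x=33.7, Hill_x=-3.9),
    "k_ef": DoseResponseParams(min_x=6.1e-5, max_x=3.5e-3, IC50_x=32.4, Hill_x=-3.9),
}

# Whole-body defaults used only to synthesize realistic input curves.
# Volumes: plasma ~0.04 L/kg, interstitium ~0.16 L/kg; liver ~4% (rat) or
# ~2.6% (human) of body weight; gadoxetate dose 25 umol/kg in both species.
RAT_WHOLEBODY_DEFAULTS = WholeBodyParams(
    k_i=2e-2, k_ef=3.5e-3, k_renal=1e-3,
    v_liver=0.04, v_spleen=0.003,
    injected_amount=0.025, injection_duration=10.0,
)
HUMAN_WHOLEBODY_DEFAULTS = WholeBodyParams(
    k_i=2e-3, k_ef=3.5e-4, k_renal=3e-4,
    k_pe=1e-3, k_ep=2e-3,
    v_liver=0.026, v_spleen=0.0025,
    injected_amount=0.025, injection_duration=10.0,
)

#: Human sampling protocol in minutes (converted to seconds on use).
HUMAN_SAMPLE_TIMES_MIN = (0, 1 / 3, 1, 3, 5, 8, 10, 13, 15, 18, 20, 23, 25, 28, 30)
RAT_SAMPLE_TIMES_S = tuple(float(t) for t in range(0, 3601, 60))


@dataclass
class RatCohortSpec:
    doses: tuple[float, ...] = (0.0, 20.0, 50.0, 200.0, 2000.0)
    n_per_dose: int = 6
    truth: dict[str, DoseResponseParams] = field(
        default_factory=lambda: dict(TABLE_1A_TRUTH))
    noise_cv: float = 0.05
    input_noise_cv: float | None = None   # spleen-curve noise; None = same as noise_cv
    omega_frac: float = 0.10      # between-rat SD as fraction of dose-predicted rate
    v_ES: float = 0.23
    sample_times_s: tuple[float, ...] = RAT_SAMPLE_TIMES_S
    wholebody: WholeBodyParams = field(default_factory=lambda: RAT_WHOLEBODY_DEFAULTS)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.doses)) != len(self.doses) or any(d < 0 for d in self.doses):
            raise ValidationError("doses must be distinct and non-negative")
        if self.n_per_dose < 1:
            raise ValidationError("n_per_dose must be >= 1")
        if self.noise_cv < 0 or self.omega_frac < 0:
            raise ValidationError("noise_cv and omega_frac must be non-negative")


@dataclass
class HumanProtocolSpec:
    sample_times_min: tuple[float, ...] = HUMAN_SAMPLE_TIMES_MIN
    noise_cv: float = 0.05
    k_i_median: float = 2e-3      # log-normal baseline distribution of k_i
    k_i_log_sd: float = 0.5
    k_ef_median: float = 2e-4
    v_ES: float = 0.23
    wholebody: WholeBodyParams = field(default_factory=lambda: HUMAN_WHOLEBODY_DEFAULTS)
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_min, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must start at 0 and increase")


def _sigma_floor(peak: float, noise_cv: float) -> float:
    """Reported per-point SD; a tiny floor keeps χ² defined on noiseless data."""
    return max(noise_cv * peak, 1e-6 * max(peak, 1e-12))


def _add_noise(ts: TimeSeries, noise_cv: float, rng: np.random.Generator) -> TimeSeries:
    sigma = _sigma_floor(ts.peak, noise_cv)
    noise = rng.normal(0.0, noise_cv * ts.peak, size=len(ts)) if noise_cv > 0 else 0.0
    return TimeSeries(times=ts.times, values=ts.values + noise,
                      sigmas=np.full(len(ts), sigma), tissue=ts.tissue)


def generate_input_function(
    species: str = "rat",
    wholebody: WholeBodyParams | None = None,
    times=None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> dict[str, TimeSeries]:
    """Spleen-surrogate and blood input curves from the whole-body model.

    Returns noise-free curves when ``noise_cv`` is 0; otherwise additive
    Gaussian noise with SD = noise_cv x peak is applied per curve.
    """
    if wholebody is None:
        wholebody = RAT_WHOLEBODY_DEFAULTS if species == "rat" else HUMAN_WHOLEBODY_DEFAULTS
    if times is None:
        times = (np.asarray(RAT_SAMPLE_TIMES_S) if species == "rat"
                 else 60.0 * np.asarray(HUMAN_SAMPLE_TIMES_MIN))
    times = np.asarray(times, dtype=float)
    out = simulate_wholebody(wholebody, times)
    curves = {"spleen": out.spleen,
              "blood_aorta": out.plasma}
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        curves = {t: _add_noise(c, noise_cv, rng) for t, c in curves.items()}
    return curves


def generate_rat_cohort(
    spec: RatCohortSpec | None = None,
) -> tuple[list[SubjectDataset], dict]:
    """Simulate the default 30-rat CKA dose-response cohort.

    For each rat j at dose d: k_x,j = dose-response mean + p_x,j with
    p_x,j ~ N(0, (omega_frac x mean)^2) truncated to keep the rate
    positive.  The rat's input (spleen) comes from the whole-body model run
    with its own rates; the liver curve is the Patlak response to that
    noise-free input.  Gaussian noise (SD = noise_cv x peak) is added to
    both curves, and the reported sigmas equal the true noise SD.

    Returns the datasets and a hidden-truth ledger sufficient to score
    every downstream stage.
    """
    spec = spec or RatCohortSpec()
    # independent streams so noise settings never perturb the biology draws
    rng, noise_rng = np.random.default_rng(spec.seed).spawn(2)
    times = np.asarray(spec.sample_times_s, dtype=float)
    cohort: list[SubjectDataset] = []
    truth_subjects = {}
    idx = 0
    for dose in spec.doses:
        for _ in range(spec.n_per_dose):
            idx += 1
            sid = f"rat{idx:02d}"
            rates = {}
            for x in ("k_i", "k_ef"):
                mean = float(evaluate_dose_response(spec.truth[x], dose))
                sd = spec.omega_frac * mean
                val = rng.normal(mean, sd) if sd > 0 else mean
                while val <= 0:
                    val = rng.normal(mean, sd)
                rates[x] = val
            wb = replace(spec.wholebody, k_i=rates["k_i"], k_ef=rates["k_ef"])
            spleen_clean = simulate_wholebody(wb, times).spleen
            patlak = PatlakParams(k_i=rates["k_i"], k_ef=rates["k_ef"], v_ES=spec.v_ES)
            liver_clean = simulate_patlak(patlak, spleen_clean, times)
            ds = SubjectDataset(
                subject_id=sid, species="rat", dose_mg_per_kg=float(dose),
                gadoxetate_dose_mmol_per_kg=spec.wholebody.injected_amount,
                injection_duration_s=spec.wholebody.injection_duration,
                curves={
                    "liver": _add_noise(liver_clean, spec.noise_cv, noise_rng),
                    "spleen": _add_noise(
                        spleen_clean,
                        spec.noise_cv if spec.input_noise_cv is None
                        else spec.input_noise_cv,
                        noise_rng),
                },
            )
            cohort.append(ds)
            truth_subjects[sid] = {
                "dose_mg_per_kg": float(dose),
                "k_i": rates["k_i"], "k_ef": rates["k_ef"], "v_ES": spec.v_ES,
            }
    truth = {
        "fixed_effects": {
            x: {"min_x": p.min_x, "max_x": p.max_x,
                "IC50_x": p.IC50_x, "Hill_x": p.Hill_x}
            for x, p in spec.truth.items()
        },
        "omega_frac": spec.omega_frac,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "subjects": truth_subjects,
    }
    return cohort, truth


def generate_human_subject(
    spec: HumanProtocolSpec | None = None,
    patient_truth: PatlakParams | None = None,
    subject_id: str = "patient01",
) -> tuple[SubjectDataset, dict]:
    """One synthetic patient on the breath-hold protocol.

    Liver, spleen and blood curves at the protocol times; when
    ``patient_truth`` is not given, a baseline k_i is drawn log-normally
    around the typical human uptake rate.
    """
    spec = spec or HumanProtocolSpec()
    rng, noise_rng = np.random.default_rng(spec.seed).spawn(2)
    times = 60.0 * np.asarray(spec.sample_times_min, dtype=float)
    if patient_truth is None:
        k_i = float(np.exp(rng.normal(np.log(spec.k_i_median), spec.k_i_log_sd)))
        k_ef = float(np.exp(rng.normal(np.log(spec.k_ef_median), spec.k_i_log_sd)))
        patient_truth = PatlakParams(k_i=k_i, k_ef=k_ef, v_ES=spec.v_ES)
    wb = replace(spec.wholebody, k_i=patient_truth.k_i, k_ef=patient_truth.k_ef)
    out = simulate_wholebody(wb, times)
    liver_clean = simulate_patlak(patient_truth, out.spleen, times)
    ds = SubjectDataset(
        subject_id=subject_id, species="human",
        gadoxetate_dose_mmol_per_kg=spec.wholebody.injected_amount,
        injection_duration_s=spec.wholebody.injection_duration,
        curves={
            "liver": _add_noise(liver_clean, spec.noise_cv, noise_rng),
            "spleen": _add_noise(out.spleen, spec.noise_cv, noise_rng),
            "blood_aorta": _add_noise(out.plasma, spec.noise_cv, noise_rng),
        },
    )
    truth = {"k_i": patient_truth.k_i, "k_ef": patient_truth.k_ef,
             "v_ES": patient_truth.v_ES, "seed": spec.seed}
    return ds, truth
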