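"""Rat-to-human translation of the drug dose-response and dose planning.

The rat Hill curve's IC50 and Hill coefficient are carried over unchanged;
the human curve is anchored at the patient's own drug-free rate:

    max_human = k_human
    min_human = max_human * (min_rat / max_rat)

so each patient keeps the rat curve's shape and relative span, scaled to
their baseline.  The maximal allowed dose is where the predicted uptake
rate crosses the lower limit of the normal-function range; a drug is usable
only if the minimal required (efficacious) dose is strictly below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import TimeSeries, ValidationError
from .doseresponse import DoseResponseParams, evaluate_dose_response
from .models import PatlakParams, simulate_patlak

__all__ = [
    "TRANSLATION_DISCLAIMER",
    "PatientBaseline",
    "DosePlanningConfig",
    "TranslationResult",
    "translate_params",
    "human_dose_response",
    "maximal_allowed_dose",
    "dosing_decision",
    "simulate_patient_under_drug",
    "plan_dose",
]

#: Mandatory caveat attached to every translation output: the rat-measured
#: dose-response is assumed to hold unchanged in humans, which is known not
#: to be strictly true (transporter orthologs and drug pharmacokinetics
#: differ between the species).  Results are illustrative, not clinical
#: dosing advice.
TRANSLATION_DISCLAIMER = (
    "Assumes the drug dose-response (IC50, Hill) measured in rats applies "
    "unchanged to humans; species differences in transporter affinity, "
    "expression and drug pharmacokinetics are not modelled. Illustrative "
    "only - not for clinical dosing."
)

OK_TO_USE = "ok_to_use"
NEED_ANOTHER_DRUG = "need_another_drug"


@dataclass
class PatientBaseline:
    """A patient's drug-free transport rates (s^-1) from their own fit."""

    patient_id: str
    k_i_human: float
    k_ef_human: float | None = None

    def __post_init__(self) -> None:
        if self.k_i_human <= 0:
            raise ValidationError("k_i_human must be positive")
        if self.k_ef_human is not None and self.k_ef_human <= 0:
            raise ValidationError("k_ef_human must be positive")


@dataclass
class DosePlanningConfig:
    """normal_lower_limit: lower bound (s^-1) of the normal-function range
    for k_i (from a reference healthy cohort, not computed here);
    minimal_required_dose: lowest efficacious dose (mg/kg)."""

    normal_lower_limit: float
    minimal_required_dose: float

    def __post_init__(self) -> None:
        if self.normal_lower_limit <= 0 or self.minimal_required_dose <= 0:
            raise ValidationError("dose-planning limits must be positive")


@dataclass
class TranslationResult:
    patient_id: str
    max_human: float
    min_human: float
    IC50: float
    Hill: float
    maximal_allowed_dose: float       # mg/kg; inf = limit never crossed
    minimal_required_dose: float
    decision: str
    disclaimer: str = TRANSLATION_DISCLAIMER

    def __post_init__(self) -> None:
        if not self.min_human < self.max_human:
            raise ValidationError("min_human must be below max_human")


def translate_params(baseline: PatientBaseline,
                     rat: DoseResponseParams) -> tuple[float, float]:
    """(max_human, min_human) for the uptake rate: the human maximum is the
    patient's own drug-free rate; the minimum keeps the rat min/max ratio."""
    max_h = baseline.k_i_human
    min_h = max_h * rat.min_x / rat.max_x
    return max_h, min_h


def _human_params(baseline: PatientBaseline, rat: DoseResponseParams) -> DoseResponseParams:
    max_h, min_h = translate_params(baseline, rat)
    return DoseResponseParams(min_x=min_h, max_x=max_h,
                              IC50_x=rat.IC50_x, Hill_x=rat.Hill_x)


def human_dose_response(baseline: PatientBaseline, rat: DoseResponseParams,
                        dose) -> np.ndarray | float:
    """Predicted human uptake rate at the given drug dose(s), using the rat
    IC50 and Hill with patient-anchored max/min."""
    return evaluate_dose_response(_human_params(baseline, rat), dose)


def maximal_allowed_dose(baseline: PatientBaseline, rat: DoseResponseParams,
                         cfg: DosePlanningConfig) -> float:
    """Highest dose (mg/kg) before the predicted rate falls below the
    normal-function lower limit L, by closed-form Hill inversion:

        D = IC50 * ((max_h - L) / (L - min_h)) ** (-1 / Hill)

    Sentinels: ``inf`` when L <= min_human (the limit is never crossed at
    any dose) and ``0`` when L >= max_human (function already below normal
    without the drug).
    """
    max_h, min_h = translate_params(baseline, rat)
    L = cfg.normal_lower_limit
    if L <= min_h:
        return math.inf
    if L >= max_h:
        return 0.0
    return rat.IC50_x * ((max_h - L) / (L - min_h)) ** (-1.0 / rat.Hill_x)


def dosing_decision(maximal_allowed: float, minimal_required: float) -> str:
    """A drug is usable only if the minimal required dose is strictly below
    the maximal allowed dose."""
    if maximal_allowed < 0 or minimal_required < 0:
        raise ValidationError("doses must be non-negative")
    return OK_TO_USE if minimal_required < maximal_allowed else NEED_ANOTHER_DRUG


def plan_dose(baseline: PatientBaseline, rat: DoseResponseParams,
              cfg: DosePlanningConfig) -> TranslationResult:
    """Full per-patient dose-planning record (Table-style row)."""
    max_h, min_h = translate_params(baseline, rat)
    mad = maximal_allowed_dose(baseline, rat, cfg)
    return TranslationResult(
        patient_id=baseline.patient_id, max_human=max_h, min_human=min_h,
        IC50=rat.IC50_x, Hill=rat.Hill_x, maximal_allowed_dose=mad,
        minimal_required_dose=cfg.minimal_required_dose,
        decision=dosing_decision(mad, cfg.minimal_required_dose),
    )


def simulate_patient_under_drug(
    baseline: PatientBaseline,
    rat: Mapping[str, DoseResponseParams],
    input_curve: TimeSeries,
    doses: Sequence[float],
    v_ES: float = 0.23,
    k_ef_fixed: float | None = None,
    eval_times=None,
) -> dict[float, TimeSeries]:
    """Family of predicted liver curves for one patient at several drug doses.

    k_i is modulated through the translated dose-response; k_ef likewise
    when the baseline provides a drug-free k_ef and ``rat`` contains a
    'k_ef' entry, otherwise it stays at ``k_ef_fixed`` (default: the
    baseline k_ef or 0).
    """
    if eval_times is None:
        eval_times = input_curve.times
    out = {}
    kef_base = baseline.k_ef_human if baseline.k_ef_human is not None else k_ef_fixed
    for dose in doses:
        ki = float(human_dose_response(baseline, rat["k_i"], dose))
        if baseline.k_ef_human is not None and "k_ef" in rat:
            kef_baseline = PatientBaseline(baseline.patient_id, baseline.k_ef_human)
            kef = float(human_dose_response(kef_baseline, rat["k_ef"], dose))
        else:
            kef = kef_base or 0.0
        params = PatlakParams(k_i=ki, k_ef=kef, v_ES=v_ES)
        out[float(dose)] = simulate_patlak(params, input_curve, eval_times)
    return out
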