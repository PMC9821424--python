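"""Hill dose-response modelling of drug-inhibited gadoxetate transport.

The hepatotoxic drug inhibits both hepatic uptake (k_i) and biliary efflux
(k_ef).  Each rat j's rate is modelled as

    k_x,j = min_x + (max_x - min_x) / (1 + (IC50_x / dose_j)^Hill_x) + p_x,j

where the first term is the population dose-response (fixed effects) and
p_x,j ~ N(0, omega_x^2) is a per-rat random effect, truncated so rates stay
positive.  Fixed effects and random-effect SDs are estimated either by a
two-stage procedure (per-rat kinetic fits, then a curve fit to the
estimates) or jointly by stochastic-approximation EM (SAEM), where the
E-step samples the individual deviations by Metropolis moves against each
rat's χ² data likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import binomtest, spearmanr

from .data import SubjectDataset, ValidationError
from .fitting import FitResult, fit_model, _residuals
from .models import PatlakParams

__all__ = [
    "DoseResponseParams",
    "TwoStageResult",
    "NLMEConfig",
    "NLMEFit",
    "evaluate_dose_response",
    "two_stage_fit",
    "nlme_fit",
    "deviation_diagnostics",
]

KINETIC_PARAMS = ("k_i", "k_ef")


@dataclass
class DoseResponseParams:
    """Hill-curve fixed effects plus random-effect SD for one kinetic rate.

    Units: min/max in s^-1, IC50 in mg/kg, Hill dimensionless (negative for
    inhibition), omega in s^-1.
    """

    min_x: float
    max_x: float
    IC50_x: float
    Hill_x: float
    omega_x: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_x < self.max_x:
            raise ValidationError("need 0 <= min_x < max_x")
        if self.IC50_x <= 0:
            raise ValidationError("IC50_x must be positive")
        if self.omega_x < 0:
            raise ValidationError("omega_x must be non-negative")


def evaluate_dose_response(p: DoseResponseParams, dose) -> np.ndarray | float:
    """Population mean rate at the given drug dose(s), mg/kg.

    Evaluated as min + (max-min)/(1 + (dose/IC50)^(-Hill)) so that dose = 0
    is exact: the curve returns max_x for Hill < 0 and min_x for Hill > 0.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValidationError("dose must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        u = np.power(dose_arr / p.IC50_x, -p.Hill_x)
    k = np.where(np.isinf(u), p.min_x,
                 p.min_x + (p.max_x - p.min_x) / (1.0 + u))
    return float(k) if np.isscalar(dose) or dose_arr.ndim == 0 else k


# ---------------------------------------------------------------------------
# Hill-curve fixed-effect fit to per-rat estimates
# ---------------------------------------------------------------------------

def _hill_from_theta(theta: np.ndarray) -> DoseResponseParams:
    log_min, log_span, log_ic50, hill = theta
    mn = math.exp(log_min)
    return DoseResponseParams(min_x=mn, max_x=mn + math.exp(log_span),
                              IC50_x=math.exp(log_ic50), Hill_x=hill)


def _fit_hill(doses: np.ndarray, rates: np.ndarray,
              theta0: np.ndarray | None = None) -> tuple[DoseResponseParams, np.ndarray]:
    """Least squares on log-rates (rates span decades; scatter is roughly
    proportional).  Parameterized to enforce 0 < min < max and IC50 > 0."""
    if theta0 is None:
        r_lo = max(float(rates.min()) * 0.5, 1e-12)
        r_hi = float(rates.max())
        pos = doses[doses > 0]
        ic0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 50.0
        theta0 = np.array([math.log(r_lo), math.log(max(r_hi - r_lo, 1e-12)),
                           math.log(ic0), -2.0])

    def resid(theta: np.ndarray) -> np.ndarray:
        p = _hill_from_theta(theta)
        pred = evaluate_dose_response(p, doses)
        return np.log(np.maximum(pred, 1e-300)) - np.log(np.maximum(rates, 1e-300))

    lo = np.array([-60.0, -60.0, math.log(1e-3), -50.0])
    hi = np.array([5.0, 5.0, math.log(1e6), 50.0])
    sol = least_squares(resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return _hill_from_theta(sol.x), sol.x


@dataclass
class TwoStageResult:
    params: dict[str, DoseResponseParams]          # per kinetic parameter
    per_subject: pd.DataFrame                      # subject, dose, k_i, k_ef, v_ES
    fits: dict[str, FitResult] = field(default_factory=dict)


def _check_cohort(cohort: Sequence[SubjectDataset]) -> None:
    doses = {d.dose_mg_per_kg for d in cohort}
    if len(doses) < 2:
        raise ValidationError("need at least two distinct dose groups")
    if 0.0 not in doses:
        raise ValidationError("cohort must include a dose-0 group")


def two_stage_fit(
    cohort: Sequence[SubjectDataset],
    kinetic_model: str = "patlak",
    input_tissue: str = "spleen",
    n_starts: int = 4,
    seed: int = 0,
) -> TwoStageResult:
    """Stage 1: fit the kinetic model per rat; stage 2: fit the Hill curve
    to the per-rat rate estimates; omega from the residual SD."""
    _check_cohort(cohort)
    rows = []
    fits = {}
    for i, ds in enumerate(cohort):
        fit = fit_model(kinetic_model, ds, n_starts=n_starts, seed=seed + i,
                        input_tissue=input_tissue)
        fits[ds.subject_id] = fit
        rows.append({
            "subject_id": ds.subject_id,
            "dose_mg_per_kg": ds.dose_mg_per_kg,
            **{n: getattr(fit.params, n) for n in fit.free_names},
        })
    table = pd.DataFrame(rows)
    doses = table["dose_mg_per_kg"].to_numpy()
    params = {}
    for x in KINETIC_PARAMS:
        rates = table[x].to_numpy()
        p, _ = _fit_hill(doses, rates)
        resid = rates - evaluate_dose_response(p, doses)
        params[x] = replace(p, omega_x=float(np.std(resid)))
    return TwoStageResult(params=params, per_subject=table, fits=fits)


# ---------------------------------------------------------------------------
# SAEM nonlinear mixed-effects estimation
# ---------------------------------------------------------------------------

@dataclass
class NLMEConfig:
    n_burnin: int = 300       # iterations with gain 1
    n_iterations: int = 200   # iterations with gain 1/k
    n_chains: int = 2         # Metropolis sweeps per iteration
    seed: int = 0
    proposal_scale: float = 0.3   # RW proposal SD as a fraction of omega
    stage1_starts: int = 4


@dataclass
class NLMEFit:
    params: dict[str, DoseResponseParams]
    individual_deviations: dict[str, dict[str, float]]   # subject -> {k_i: p, k_ef: p}
    doses: dict[str, float]
    loglik_trace: np.ndarray
    seed: int
    converged: bool = True
    acceptance_rate: float = float("nan")


def nlme_fit(
    cohort: Sequence[SubjectDataset],
    kinetic_model: str = "patlak",
    config: NLMEConfig | None = None,
    input_tissue: str = "spleen",
    init: TwoStageResult | None = None,
) -> NLMEFit:
    """Joint estimation of the Hill fixed effects and random-effect SDs.

    Stochastic-approximation EM: each rat's deviations p_x,j are sampled by
    random-walk Metropolis against exp(-χ²_j/2) x N(0, omega_x²) with
    proposals rejected when the implied rate would be non-positive; the
    M-step refits the Hill curve to stochastically-averaged individual
    rates and updates omega from averaged squared deviations.  Gain is 1
    during burn-in and 1/k afterwards.  Deterministic given the seed.

    Each rat's v_ES is fixed at its stage-1 estimate; the random effects
    act on the transport rates only, independently for k_i and k_ef.
    """
    cfg = config or NLMEConfig()
    _check_cohort(cohort)
    if init is None:
        init = two_stage_fit(cohort, kinetic_model, input_tissue,
                             n_starts=cfg.stage1_starts, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    n = len(cohort)
    doses = np.array([d.dose_mg_per_kg for d in cohort])
    ids = [d.subject_id for d in cohort]
    table = init.per_subject.set_index("subject_id")

    # fixed per-rat context from stage 1
    v_es = np.array([table.loc[i, "v_ES"] for i in ids])
    k = {x: np.array([table.loc[i, x] for i in ids]) for x in KINETIC_PARAMS}

    fixed = {x: init.params[x] for x in KINETIC_PARAMS}
    omega = {x: max(init.params[x].omega_x,
                    0.02 * init.params[x].max_x) for x in KINETIC_PARAMS}
    theta_warm = {x: None for x in KINETIC_PARAMS}

    def chi2_of(j: int, ki: float, kef: float) -> float:
        p = PatlakParams(k_i=ki, k_ef=kef, v_ES=float(v_es[j]))
        r = _residuals("patlak", p, cohort[j], input_tissue, ("liver",))
        return float(np.dot(r, r))

    chi2_cur = np.array([chi2_of(j, k["k_i"][j], k["k_ef"][j]) for j in range(n)])
    k_bar = {x: k[x].copy() for x in KINETIC_PARAMS}
    p2_bar = {x: np.zeros(n) for x in KINETIC_PARAMS}
    for x in KINETIC_PARAMS:
        mean = evaluate_dose_response(fixed[x], doses)
        p2_bar[x] = (k[x] - mean) ** 2

    total = cfg.n_burnin + cfg.n_iterations
    trace = np.empty(total)
    n_prop = 0
    n_acc = 0
    for it in range(total):
        gain = 1.0 if it < cfg.n_burnin else 1.0 / (it - cfg.n_burnin + 1)
        mean = {x: evaluate_dose_response(fixed[x], doses) for x in KINETIC_PARAMS}
        for _ in range(cfg.n_chains):
            for x in KINETIC_PARAMS:
                other = "k_ef" if x == "k_i" else "k_i"
                step = cfg.proposal_scale * omega[x]
                for j in range(n):
                    prop = k[x][j] + rng.normal(0.0, step)
                    n_prop += 1
                    if prop <= 0:
                        continue
                    if x == "k_i":
                        c_new = chi2_of(j, prop, k[other][j])
                    else:
                        c_new = chi2_of(j, k[other][j], prop)
                    p_old = k[x][j] - mean[x][j]
                    p_new = prop - mean[x][j]
                    log_a = (-0.5 * (c_new - chi2_cur[j])
                             - (p_new ** 2 - p_old ** 2) / (2 * omega[x] ** 2))
                    if log_a >= 0 or rng.random() < math.exp(log_a):
                        k[x][j] = prop
                        chi2_cur[j] = c_new
                        n_acc += 1
        # stochastic-approximation smoothing of sufficient statistics
        for x in KINETIC_PARAMS:
            k_bar[x] = (1 - gain) * k_bar[x] + gain * k[x]
        # M-step: refit fixed effects to smoothed rates, update omegas
        for x in KINETIC_PARAMS:
            p_fit, theta_warm[x] = _fit_hill(doses, k_bar[x], theta_warm[x])
            fixed[x] = p_fit
            dev2 = (k[x] - evaluate_dose_response(p_fit, doses)) ** 2
            p2_bar[x] = (1 - gain) * p2_bar[x] + gain * dev2
            omega[x] = max(math.sqrt(float(np.mean(p2_bar[x]))), 1e-12)
        ll = -0.5 * float(np.sum(chi2_cur))
        for x in KINETIC_PARAMS:
            dev = k[x] - evaluate_dose_response(fixed[x], doses)
            ll += float(np.sum(-0.5 * dev ** 2 / omega[x] ** 2 - math.log(omega[x])))
        trace[it] = ll

    deviations = {}
    for j, sid in enumerate(ids):
        deviations[sid] = {
            x: float(k_bar[x][j] - evaluate_dose_response(fixed[x], doses[j]))
            for x in KINETIC_PARAMS
        }
    params = {x: replace(fixed[x], omega_x=float(omega[x])) for x in KINETIC_PARAMS}
    # crude convergence check: late-trace drift small relative to its spread
    tail = trace[-max(cfg.n_iterations // 2, 1):]
    converged = bool(np.ptp(tail) < 50.0 or np.std(tail) < 5.0)
    return NLMEFit(params=params, individual_deviations=deviations,
                   doses={sid: float(d) for sid, d in zip(ids, doses)},
                   loglik_trace=trace, seed=cfg.seed, converged=converged,
                   acceptance_rate=n_acc / max(n_prop, 1))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def deviation_diagnostics(fit: NLMEFit) -> tuple[pd.DataFrame, dict]:
    """Per-rat random-effect deviations with dose labels, plus summary tests.

    The summary checks that deviations vary evenly around zero (sign test)
    and are not systematically dose-correlated (Spearman test per
    parameter).
    """
    rows = []
    for sid, devs in fit.individual_deviations.items():
        rows.append({"subject_id": sid, "dose_mg_per_kg": fit.doses[sid], **devs})
    table = pd.DataFrame(rows)
    summary: dict[str, dict[str, float]] = {}
    for x in KINETIC_PARAMS:
        d = table[x].to_numpy()
        nonzero = d[d != 0]
        if nonzero.size:
            sign_p = float(binomtest((nonzero > 0).sum(), nonzero.size, 0.5).pvalue)
        else:
            sign_p = 1.0
        if np.unique(table["dose_mg_per_kg"]).size > 1 and np.std(d) > 0:
            rho, rho_p = spearmanr(table["dose_mg_per_kg"], d)
        else:
            rho, rho_p = 0.0, 1.0
        summary[x] = {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            "sign_test_p": sign_p,
            "dose_spearman_rho": float(rho),
            "dose_spearman_p": float(rho_p),
        }
    return table, summary
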