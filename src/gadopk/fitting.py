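"""Parameter estimation and identifiability analysis.

Fits any of the three kinetic models to a subject's concentration curves by
weighted least squares (χ² cost), with multistart local optimization in
log-parameter space.  Identifiability is quantified by profile likelihood:
one parameter is stepped away from its optimum while all others are
re-optimized, and the 95% confidence interval is bounded where the profiled
cost exceeds the optimal cost plus the 95th percentile of the χ²
distribution with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

from .data import SubjectDataset, TimeSeries, ValidationError
from .models import (
    PatlakParams,
    PerfusionParams,
    WholeBodyParams,
    simulate_patlak,
    simulate_perfusion,
    simulate_wholebody,
)

__all__ = [
    "FitResult",
    "ProfileConfig",
    "ProfileResult",
    "CIComparison",
    "chi2_cost",
    "fit_model",
    "goodness_of_fit",
    "profile_likelihood",
    "profile_parameter",
    "compare_model_cis",
    "MODEL_BOUNDS",
]


class OptimizationError(RuntimeError):
    """Raised when every optimization start fails."""


# Allowed parameter ranges (s^-1 for rates).  The hepatic rates have a lower
# limit of 1e-8 for the Patlak and Perfusion models and 1e-5 for the
# Whole-body model; open profile ends are reported against these limits.
MODEL_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "patlak": {"k_i": (1e-8, 1.0), "k_ef": (1e-8, 1.0), "v_ES": (1e-3, 1.0)},
    "perfusion": {
        "F_p": (1e-4, 10.0),
        "k_i": (1e-8, 1.0),
        "k_ef": (1e-8, 1.0),
        "v_E": (1e-3, 0.95),
    },
    "wholebody": {
        "k_i": (1e-5, 1.0),
        "k_ef": (1e-5, 1.0),
        "k_pe": (1e-6, 1.0),
        "k_ep": (1e-6, 1.0),
        "k_ps": (1e-6, 1.0),
        "k_sp": (1e-6, 1.0),
        "k_renal": (1e-6, 1.0),
        "v_p": (1e-3, 1.0),
        "v_EES": (1e-3, 1.0),
    },
}

# Free parameters per model.  The whole-body fit frees the exchange/
# elimination rates and the body pool volumes alongside the hepatic rates,
# reflecting the model's real complexity (the tissue volumes are not known
# a priori); this is what renders its hepatic rates poorly identifiable.
_DEFAULT_FREE: dict[str, tuple[str, ...]] = {
    "patlak": ("k_i", "k_ef", "v_ES"),
    "perfusion": ("F_p", "k_i", "k_ef", "v_E"),
    "wholebody": ("k_i", "k_ef", "k_pe", "k_ep", "k_ps", "k_sp", "k_renal",
                  "v_p", "v_EES"),
}

_PARAM_CLS = {"patlak": PatlakParams, "perfusion": PerfusionParams, "wholebody": WholeBodyParams}


@dataclass
class FitResult:
    model_name: str
    params: object
    cost: float
    n_obs: int
    n_free: int
    gof_pass: bool
    n_starts: int
    seed: int
    free_names: tuple[str, ...] = ()
    input_tissue: str = "spleen"

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self.params, n) for n in self.free_names])


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

def chi2_cost(simulated: TimeSeries, observed: TimeSeries) -> float:
    """Weighted least-squares cost  Σ_t ((y_t − ŷ_t)/σ_t)²."""
    if simulated.tissue != observed.tissue:
        raise ValidationError(
            f"tissue mismatch: {simulated.tissue!r} vs {observed.tissue!r}")
    if simulated.times.shape != observed.times.shape or not np.allclose(
            simulated.times, observed.times):
        raise ValidationError("time grids of simulated and observed curves differ")
    if observed.sigmas is None:
        raise ValidationError("observed curve carries no measurement sigmas")
    r = (observed.values - simulated.values) / observed.sigmas
    return float(np.dot(r, r))


def goodness_of_fit(fit: FitResult, alpha: float = 0.95, dof: int | None = None) -> bool:
    """χ² goodness-of-fit test: pass iff cost ≤ χ²-quantile(alpha, dof).

    Default dof is the number of observations (no correction for fitted
    parameters); pass ``dof=fit.n_obs - fit.n_free`` for the corrected
    convention.
    """
    d = fit.n_obs if dof is None else dof
    return bool(fit.cost <= chi2.ppf(alpha, d))


# ---------------------------------------------------------------------------
# Model prediction plumbing
# ---------------------------------------------------------------------------

def _fitted_tissues(model_name: str, dataset: SubjectDataset) -> tuple[str, ...]:
    if model_name == "wholebody":
        return tuple(t for t in ("liver", "spleen") if t in dataset)
    return ("liver",)


def _predict(model_name: str, params, dataset: SubjectDataset,
             input_tissue: str) -> dict[str, TimeSeries]:
    """Simulate the model observables at the dataset's measurement times."""
    if model_name == "patlak":
        liver = dataset["liver"]
        sim = simulate_patlak(params, dataset[input_tissue], liver.times)
        return {"liver": sim}
    if model_name == "perfusion":
        liver = dataset["liver"]
        if input_tissue == "dual":
            sim = simulate_perfusion(params, arterial=dataset["blood_aorta"],
                                     portal=dataset["blood_portal"],
                                     eval_times=liver.times)
        else:
            sim = simulate_perfusion(params, single_input=dataset[input_tissue],
                                     eval_times=liver.times)
        return {"liver": sim}
    if model_name == "wholebody":
        times = dataset["liver"].times
        out = simulate_wholebody(params, times)
        preds = {"liver": out.liver}
        if "spleen" in dataset:
            sp = dataset["spleen"]
            if sp.times.shape == times.shape and np.allclose(sp.times, times):
                preds["spleen"] = out.spleen
            else:
                preds["spleen"] = simulate_wholebody(params, sp.times).spleen
        return preds
    raise ValidationError(f"unknown model {model_name!r}")


def _build_params(model_name: str, base, free_names: Sequence[str],
                  values: np.ndarray):
    return replace(base, **dict(zip(free_names, values)))


def _base_params(model_name: str, dataset: SubjectDataset, base):
    if base is not None:
        return base
    if model_name == "patlak":
        return PatlakParams(k_i=1e-3, k_ef=1e-4, v_ES=0.23)
    if model_name == "perfusion":
        return PerfusionParams(F_p=0.02, k_i=1e-3, k_ef=1e-4, v_E=0.23)
    return WholeBodyParams(
        injected_amount=dataset.gadoxetate_dose_mmol_per_kg,
        injection_duration=dataset.injection_duration_s,
    )


def _residuals(model_name: str, params, dataset: SubjectDataset,
               input_tissue: str, tissues: Sequence[str]) -> np.ndarray:
    preds = _predict(model_name, params, dataset, input_tissue)
    parts = []
    for t in tissues:
        obs = dataset[t]
        parts.append((obs.values - preds[t].values) / obs.sigmas)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Multistart fit
# ---------------------------------------------------------------------------

def fit_model(
    model_name: str,
    dataset: SubjectDataset,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    input_tissue: str = "spleen",
    free: Sequence[str] | None = None,
    base_params=None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Multistart weighted least-squares fit of one model to one subject.

    Optimization runs in log10-parameter space with bound constraints;
    starts are drawn log-uniformly within the bounds from ``seed``, so the
    result is deterministic.  ``x0`` (linear scale, free parameters) adds an
    explicit first start.
    """
    if model_name not in _PARAM_CLS:
        raise ValidationError(f"unknown model {model_name!r}")
    if "liver" not in dataset:
        raise ValidationError("dataset lacks a liver curve")
    free_names = tuple(free or _DEFAULT_FREE[model_name])
    all_bounds = dict(MODEL_BOUNDS[model_name])
    if bounds:
        all_bounds.update(bounds)
    lo = np.log10([all_bounds[n][0] for n in free_names])
    hi = np.log10([all_bounds[n][1] for n in free_names])
    base = _base_params(model_name, dataset, base_params)
    tissues = _fitted_tissues(model_name, dataset)

    def resid(theta_log: np.ndarray) -> np.ndarray:
        p = _build_params(model_name, base, free_names, 10.0 ** theta_log)
        return _residuals(model_name, p, dataset, input_tissue, tissues)

    rng = np.random.default_rng(seed)
    starts = [lo + rng.random(len(free_names)) * (hi - lo) for _ in range(n_starts)]
    if x0 is not None:
        starts.insert(0, np.clip(np.log10(np.asarray(x0, dtype=float)), lo, hi))

    best = None
    failures = []
    for s in starts:
        try:
            sol = least_squares(resid, s, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # noqa: BLE001 - report with the start
            failures.append((s, exc))
            continue
        cost = float(2 * sol.cost)  # least_squares cost is 0.5 * sum(res^2)
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise OptimizationError(
            f"all {len(starts)} starts failed for {model_name}: {failures}")

    cost, theta = best
    params = _build_params(model_name, base, free_names, 10.0 ** theta)
    n_obs = sum(len(dataset[t]) for t in tissues)
    fit = FitResult(
        model_name=model_name, params=params, cost=cost, n_obs=n_obs,
        n_free=len(free_names), gof_pass=False, n_starts=len(starts),
        seed=seed, free_names=free_names, input_tissue=input_tissue,
    )
    fit.gof_pass = goodness_of_fit(fit)
    return fit


# ---------------------------------------------------------------------------
# Profile likelihood
# ---------------------------------------------------------------------------

@dataclass
class ProfileConfig:
    max_steps: int = 60
    initial_factor: float = 1.1
    min_rel_step: float = 1e-3
    max_factor: float = 4.0
    confidence: float = 0.95
    # step doubles when the cost gain of the last step is below this fraction
    # of the cutoff gap
    slow_gain_fraction: float = 0.1


@dataclass
class ProfileResult:
    """Profiled cost curve and confidence interval for one parameter.

    ``ci_lower``/``ci_upper`` are the interpolated crossing points of the
    cutoff, or the allowed parameter limit when the profile never crossed it
    in that direction (flagged by ``lower_open``/``upper_open``).
    """

    param_name: str
    estimate: float
    grid: np.ndarray
    costs: np.ndarray
    ci_lower: float
    ci_upper: float
    cutoff: float
    lower_open: bool = False
    upper_open: bool = False

    @property
    def length(self) -> float:
        return self.ci_upper - self.ci_lower

    def contains(self, value: float) -> bool:
        return self.ci_lower <= value <= self.ci_upper


def profile_parameter(
    reoptimize: Callable[[float, object], tuple[float, object]],
    estimate: float,
    optimal_cost: float,
    bounds: tuple[float, float],
    param_name: str = "theta",
    config: ProfileConfig | None = None,
    warm_start=None,
) -> ProfileResult:
    """Generic profile-likelihood engine over one positive parameter.

    ``reoptimize(value, warm)`` returns the cost minimized over all other
    parameters with the profiled parameter fixed at ``value``, plus an opaque
    warm-start object handed to the next call.  Steps are multiplicative,
    with the factor doubling (in log) when the cost climbs slowly and
    halving when the cutoff is overshot, until the relative step is below
    ``min_rel_step``; the CI bound is then linearly interpolated across the
    cutoff.  Hitting the bound or ``max_steps`` first leaves that side open.
    """
    cfg = config or ProfileConfig()
    cutoff = optimal_cost + float(chi2.ppf(cfg.confidence, 1))
    lo, hi = bounds
    pts: list[tuple[float, float]] = [(estimate, optimal_cost)]
    ci = {+1: hi, -1: lo}
    open_end = {+1: True, -1: True}

    for direction in (+1, -1):
        cur, cost_cur = estimate, optimal_cost
        warm = warm_start
        factor = cfg.initial_factor
        steps = 0
        while steps < cfg.max_steps:
            cand = cur * factor if direction > 0 else cur / factor
            clamped = False
            if direction > 0 and cand >= hi:
                cand, clamped = hi, True
            if direction < 0 and cand <= lo:
                cand, clamped = lo, True
            try:
                cost, warm_c = reoptimize(cand, warm)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"profile step at {param_name}={cand:g} failed: {exc}")
                cost, warm_c = np.inf, warm
            steps += 1
            if cost > cutoff:
                if factor > 1 + cfg.min_rel_step and not clamped:
                    factor = np.sqrt(factor)
                    continue
                pts.append((cand, cost))
                if np.isfinite(cost):
                    frac = (cutoff - cost_cur) / (cost - cost_cur)
                    ci[direction] = cur + (cand - cur) * frac
                else:
                    ci[direction] = cur
                open_end[direction] = False
                break
            pts.append((cand, cost))
            if clamped:
                ci[direction] = cand  # reached allowed limit below cutoff: open
                break
            if cost - cost_cur < cfg.slow_gain_fraction * (cutoff - optimal_cost):
                factor = min(factor * factor, cfg.max_factor)
            cur, cost_cur, warm = cand, cost, warm_c

    pts.sort()
    grid = np.array([p[0] for p in pts])
    costs = np.array([p[1] for p in pts])
    return ProfileResult(
        param_name=param_name, estimate=estimate, grid=grid, costs=costs,
        ci_lower=ci[-1], ci_upper=ci[+1], cutoff=cutoff,
        lower_open=open_end[-1], upper_open=open_end[+1],
    )


def profile_likelihood(
    model_name: str,
    dataset: SubjectDataset,
    fit: FitResult,
    param_name: str,
    config: ProfileConfig | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> ProfileResult:
    """Profile one kinetic parameter of a fitted model.

    At each profile step, all other free parameters are re-optimized
    (warm-started from the neighbouring step) in log space.
    """
    if param_name not in fit.free_names:
        raise ValidationError(f"{param_name!r} is not a free parameter of this fit")
    all_bounds = dict(MODEL_BOUNDS[model_name])
    if bounds:
        all_bounds.update(bounds)
    idx = fit.free_names.index(param_name)
    others = [n for n in fit.free_names if n != param_name]
    base = fit.params
    if model_name == "wholebody":
        base = replace(base, injected_amount=dataset.gadoxetate_dose_mmol_per_kg,
                       injection_duration=dataset.injection_duration_s)
    tissues = _fitted_tissues(model_name, dataset)
    input_tissue = fit.input_tissue
    lo = np.log10([all_bounds[n][0] for n in others])
    hi = np.log10([all_bounds[n][1] for n in others])
    warm0 = np.clip(np.log10([getattr(fit.params, n) for n in others]), lo, hi)

    def reopt(value: float, warm):
        warm = warm0 if warm is None else warm

        def resid(theta_log: np.ndarray) -> np.ndarray:
            vals = dict(zip(others, 10.0 ** theta_log))
            vals[param_name] = value
            p = replace(base, **vals)
            return _residuals(model_name, p, dataset, input_tissue, tissues)

        if others:
            sol = least_squares(resid, np.clip(warm, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-9, ftol=1e-9, gtol=1e-9)
            return float(2 * sol.cost), sol.x
        r = resid(np.empty(0))
        return float(np.dot(r, r)), warm

    return profile_parameter(
        reopt, estimate=float(getattr(fit.params, param_name)),
        optimal_cost=fit.cost, bounds=all_bounds[param_name],
        param_name=param_name, config=config, warm_start=None,
    )


# ---------------------------------------------------------------------------
# CI comparison across models
# ---------------------------------------------------------------------------

@dataclass
class CIComparison:
    """Per-model CI lengths and pairwise subset relations for one parameter
    profiled under several models on the same dataset(s)."""

    lengths: dict[str, np.ndarray]
    mean_length: dict[str, float]
    subset_fraction: dict[tuple[str, str], float]
    length_ratio: dict[tuple[str, str], float]


def compare_model_cis(
    profiles: Mapping[str, "ProfileResult | Sequence[ProfileResult]"],
) -> CIComparison:
    """Compare confidence intervals of the same parameter across models.

    ``profiles`` maps model name to one ProfileResult or to a sequence of
    them (one per dataset, aligned across models).  Reports CI lengths and,
    for each ordered model pair (a, b), the fraction of datasets in which
    a's CI is a subset of b's.
    """
    norm: dict[str, list[ProfileResult]] = {}
    for name, p in profiles.items():
        norm[name] = [p] if isinstance(p, ProfileResult) else list(p)
    n_sets = {len(v) for v in norm.values()}
    if len(n_sets) != 1:
        raise ValidationError("all models must provide the same number of profiles")
    lengths = {m: np.array([p.length for p in v]) for m, v in norm.items()}
    mean_length = {m: float(np.mean(v)) for m, v in lengths.items()}
    subset, ratio = {}, {}
    for a in norm:
        for b in norm:
            if a == b:
                continue
            inside = [
                pa.ci_lower >= pb.ci_lower - 1e-15 and pa.ci_upper <= pb.ci_upper + 1e-15
                for pa, pb in zip(norm[a], norm[b])
            ]
            subset[(a, b)] = float(np.mean(inside))
            ratio[(a, b)] = float(mean_length[a] / mean_length[b]) if mean_length[b] else np.inf
    return CIComparison(lengths=lengths, mean_length=mean_length,
                        subset_fraction=subset, length_ratio=ratio)
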