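"""Cost evaluation, multistart estimation, GOF, and profile likelihood."""

import numpy as np
import pytest
from scipy.stats import chi2, spearmanr

from gadopk.data import TimeSeries, ValidationError
from gadopk.fitting import (
    ProfileResult,
    chi2_cost,
    compare_model_cis,
    fit_model,
    goodness_of_fit,
    profile_likelihood,
    profile_parameter,
)
from gadopk.synthetic import RatCohortSpec, generate_rat_cohort


def _ts(values, sigmas=None, tissue="liver", times=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float) if times is None else times
    return TimeSeries(times=times, values=values, sigmas=sigmas, tissue=tissue)


class TestChi2Cost:
    def test_perfect_fit_is_zero(self):
        obs = _ts([1.0, 2.0, 3.0], sigmas=[0.1, 0.1, 0.1])
        sim = _ts([1.0, 2.0, 3.0])
        assert chi2_cost(sim, obs) == 0.0

    def test_one_sigma_residual(self):
        obs = _ts([1.0], sigmas=[0.25])
        sim = _ts([1.25])
        assert chi2_cost(sim, obs) == pytest.approx(1.0)

    def test_two_point_hand_value(self):
        # residuals of 2 sigma and -1 sigma: cost = 4 + 1 = 5
        obs = _ts([1.0, 1.0], sigmas=[0.5, 0.5])
        sim = _ts([1.0 - 2 * 0.5, 1.0 + 0.5])
        assert chi2_cost(sim, obs) == pytest.approx(5.0)

    def test_mismatched_grids_rejected(self):
        obs = _ts([1.0, 2.0], sigmas=[0.1, 0.1])
        sim = _ts([1.0, 2.0], times=np.array([0.0, 2.0]))
        with pytest.raises(ValidationError):
            chi2_cost(sim, obs)


class TestFitModel:
    def test_noiseless_patlak_recovery(self, noiseless_rat):
        ds, truth = noiseless_rat
        fit = fit_model("patlak", ds, n_starts=8, seed=2)
        for name in ("k_i", "k_ef", "v_ES"):
            assert getattr(fit.params, name) == pytest.approx(truth[name], rel=1e-3)
        assert fit.gof_pass

    def test_refit_same_seed_identical(self, noiseless_rat):
        ds, _ = noiseless_rat
        a = fit_model("patlak", ds, n_starts=5, seed=7)
        b = fit_model("patlak", ds, n_starts=5, seed=7)
        assert a.cost == b.cost
        assert np.array_equal(a.free_values(), b.free_values())

    def test_single_vs_many_starts_agree_noiseless(self, noiseless_rat):
        ds, _ = noiseless_rat
        few = fit_model("patlak", ds, n_starts=1, seed=0)
        many = fit_model("patlak", ds, n_starts=50, seed=0)
        np.testing.assert_allclose(few.free_values(), many.free_values(), rtol=1e-4)

    def test_noisy_recovery_median_error(self):
        """k_i median relative error < 10% over replicates with 5% noise on
        the fitted liver data (input treated as known)."""
        errs = []
        for rep in range(20):
            spec = RatCohortSpec(doses=(0.0, 50.0), n_per_dose=1, noise_cv=0.05,
                                 input_noise_cv=0.0, omega_frac=0.0,
                                 seed=1000 + rep)
            cohort, truth = generate_rat_cohort(spec)
            ds = cohort[0]
            tr = truth["subjects"][ds.subject_id]
            fit = fit_model("patlak", ds, n_starts=3, seed=rep)
            errs.append(abs(fit.params.k_i - tr["k_i"]) / tr["k_i"])
        assert np.median(errs) < 0.10


class TestGoodnessOfFit:
    def test_zero_cost_passes(self):
        from gadopk.fitting import FitResult
        fit = FitResult("patlak", None, cost=0.0, n_obs=10, n_free=3,
                        gof_pass=False, n_starts=1, seed=0)
        assert goodness_of_fit(fit)

    def test_just_above_quantile_fails(self):
        from gadopk.fitting import FitResult
        cut = chi2.ppf(0.95, 10)  # ~18.307 from standard tables
        fit = FitResult("patlak", None, cost=cut + 1e-6, n_obs=10, n_free=3,
                        gof_pass=False, n_starts=1, seed=0)
        assert not goodness_of_fit(fit)
        fit.cost = cut - 1e-6
        assert goodness_of_fit(fit)

    def test_pass_rate_calibrated(self):
        """On correctly specified noise (noisy liver, known input) the 95%
        GOF test passes ~95% of fits."""
        passes = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = RatCohortSpec(doses=(0.0, 200.0), n_per_dose=1, noise_cv=0.05,
                                 input_noise_cv=0.0, omega_frac=0.0,
                                 seed=20000 + rep)
            cohort, _ = generate_rat_cohort(spec)
            fit = fit_model("patlak", cohort[0], n_starts=2, seed=rep)
            passes += fit.gof_pass
        assert 0.90 <= passes / n_rep <= 0.99


class TestProfileEngine:
    def test_quadratic_cost_analytic_ci(self):
        """Quadratic profile: CI = estimate +/- SE*sqrt(chi2_0.95(1))."""
        se, theta = 0.5, 2.0
        prof = profile_parameter(lambda v, w: (((v - theta) / se) ** 2, w),
                                 estimate=theta, optimal_cost=0.0,
                                 bounds=(1e-6, 100.0))
        half = se * np.sqrt(chi2.ppf(0.95, 1))
        assert prof.ci_lower == pytest.approx(theta - half, rel=1e-3)
        assert prof.ci_upper == pytest.approx(theta + half, rel=1e-3)
        assert not prof.lower_open and not prof.upper_open

    def test_flat_cost_open_both_directions(self):
        prof = profile_parameter(lambda v, w: (0.0, w), estimate=1.0,
                                 optimal_cost=0.0, bounds=(1e-8, 1.0))
        assert prof.lower_open and prof.upper_open
        assert prof.ci_lower == pytest.approx(1e-8)
        assert prof.ci_upper == pytest.approx(1.0)

    def test_profile_costs_above_optimum_and_ci_contains_estimate(self, noiseless_rat):
        ds, _ = noiseless_rat
        fit = fit_model("patlak", ds, n_starts=4, seed=1)
        prof = profile_likelihood("patlak", ds, fit, "k_i")
        assert np.all(prof.costs >= fit.cost - 1e-6)
        assert prof.contains(prof.estimate)

    def test_unknown_parameter_rejected(self, noiseless_rat):
        ds, _ = noiseless_rat
        fit = fit_model("patlak", ds, n_starts=2, seed=1)
        with pytest.raises(ValidationError):
            profile_likelihood("patlak", ds, fit, "F_p")


class TestCompareCIs:
    def _prof(self, lo, hi, name="k_i"):
        return ProfileResult(param_name=name, estimate=(lo + hi) / 2,
                             grid=np.array([lo, hi]), costs=np.array([4.0, 4.0]),
                             ci_lower=lo, ci_upper=hi, cutoff=3.84)

    def test_identical_profiles(self):
        rep = compare_model_cis({"a": self._prof(1, 2), "b": self._prof(1, 2)})
        assert rep.subset_fraction[("a", "b")] == 1.0
        assert rep.mean_length["a"] == rep.mean_length["b"]

    def test_nested_cis(self):
        rep = compare_model_cis({"a": self._prof(1, 2), "b": self._prof(0.5, 3)})
        assert rep.subset_fraction[("a", "b")] == 1.0
        assert rep.subset_fraction[("b", "a")] == 0.0
        assert rep.length_ratio[("a", "b")] == pytest.approx(1.0 / 2.5)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValidationError):
            compare_model_cis({"a": [self._prof(1, 2)],
                               "b": [self._prof(1, 2), self._prof(1, 3)]})


def test_ki_recovery_correlates_with_truth(default_cohort):
    """Fitted Patlak k_i tracks the per-rat truth: Spearman rho > 0.95 at 5% noise."""
    cohort, truth = default_cohort
    est, tru = [], []
    for ds in cohort:
        fit = fit_model("patlak", ds, n_starts=3, seed=11)
        est.append(fit.params.k_i)
        tru.append(truth["subjects"][ds.subject_id]["k_i"])
    rho, _ = spearmanr(est, tru)
    assert rho > 0.95
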