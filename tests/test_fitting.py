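"""Specificity-constant estimation, global fitting, profiles, selectivity."""

import numpy as np
import pytest

from raskinetics.fitting import (FitFailure, FitResult,
                                 estimate_specificity_constant, fit_global,
                                 profile_specificity, selectivity_ratio)
from raskinetics.mechanism import (AssayDesign, KineticParameters,
                                   ProgressCurve, simulate_progress)
from raskinetics.synthetic import (NoiseModel, build_ras_titration_suite,
                                   simulate_suite)


def _exp_curve(k, ptot=100e-9, s0=1e-6, n=201, t_end=2300.0,
               sigma=0.0, rng=None):
    t = np.linspace(0.0, t_end, n)
    amc = s0 * (1 - np.exp(-k * ptot * t))
    if sigma > 0:
        amc = amc + rng.normal(0.0, sigma * s0, size=n)
    design = AssayDesign(protease_total=ptot, ras_total=0.0,
                         reporter_total=s0, time_grid=t)
    return ProgressCurve(time=t, amc=amc, design=design,
                         noise_sigma=sigma * s0)


class TestSpecificityConstant:
    def test_noiseless_recovery(self):
        est = estimate_specificity_constant(_exp_curve(1e4))
        assert est.value == pytest.approx(1e4, rel=1e-4)

    def test_flat_curve_raises(self):
        t = np.linspace(0.0, 100.0, 50)
        design = AssayDesign(protease_total=0.0, ras_total=0.0,
                             reporter_total=1e-6, time_grid=t)
        flat = ProgressCurve(time=t, amc=np.zeros_like(t), design=design)
        with pytest.raises(FitFailure):
            estimate_specificity_constant(flat)

    def test_three_sigma_coverage(self):
        """Across 100 seeded 1 %-noise replicates the estimate lands
        within 3 standard errors of truth at least 95 % of the time."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            est = estimate_specificity_constant(
                _exp_curve(1e4, sigma=0.01, rng=rng))
            if abs(est.value - 1e4) <= 3 * est.stderr:
                hits += 1
        assert hits >= 95


@pytest.fixture(scope="module")
def noiseless_fit(active_suite_noiseless_mod, active_curves_noiseless_mod):
    return fit_global(active_suite_noiseless_mod,
                      active_curves_noiseless_mod,
                      n_starts=4, n_polish=2, seed=0)


@pytest.fixture(scope="module")
def active_suite_noiseless_mod():
    from raskinetics.synthetic import REFERENCE_TRUTH
    return build_ras_titration_suite(
        "active", REFERENCE_TRUTH[("I", "active")], "imidazole", 1e-3,
        noise=NoiseModel(sigma=0.0, seed=0))


@pytest.fixture(scope="module")
def active_curves_noiseless_mod(active_suite_noiseless_mod):
    return simulate_suite(active_suite_noiseless_mod, noisy=False)


class TestGlobalFit:
    def test_noiseless_recovery_is_exact(self, noiseless_fit,
                                         active_suite_noiseless_mod):
        truth = active_suite_noiseless_mod.truth
        for name in ("K_S", "k_2", "K_P", "k_rep"):
            assert noiseless_fit.estimates[name] == pytest.approx(
                getattr(truth, name), rel=1e-3), name
        assert noiseless_fit.specificity == pytest.approx(
            truth.specificity, rel=1e-3)

    def test_specificity_is_exact_ratio(self, noiseless_fit):
        assert noiseless_fit.specificity == (
            noiseless_fit.estimates["k_2"] / noiseless_fit.estimates["K_S"])

    def test_residuals_finite_per_curve(self, noiseless_fit):
        assert len(noiseless_fit.residuals) == 6
        for r in noiseless_fit.residuals:
            assert np.all(np.isfinite(r))

    def test_start_log_monotone_best(self, noiseless_fit):
        """Best-so-far objective never increases over polished starts."""
        ssrs = [s["ssr"] for s in noiseless_fit.starts if s["polished"]
                and np.isfinite(s.get("ssr", np.inf))]
        best = np.minimum.accumulate(ssrs)
        assert np.all(np.diff(best) <= 0)
        assert noiseless_fit.ssr <= min(ssrs) * (1 + 1e-9)

    def test_curve_count_mismatch_rejected(self, active_suite_noiseless_mod,
                                           active_curves_noiseless_mod):
        with pytest.raises(ValueError, match="one-to-one"):
            fit_global(active_suite_noiseless_mod,
                       active_curves_noiseless_mod[:-1])

    def test_ratio_better_identified_than_parts(self):
        """When K_S sits far above the titration range, the fitted ratio
        k_2/K_S carries much less relative uncertainty than k_2 or K_S."""
        truth = KineticParameters(K_S=100e-6, k_2=1.372, K_P=0.5e-6,
                                  k_rep=1e4)
        suite = build_ras_titration_suite(
            "active", truth, noise=NoiseModel(sigma=0.01, seed=5))
        curves = simulate_suite(suite)
        fit = fit_global(suite, curves, n_starts=4, n_polish=2, seed=0)
        rel = {n: fit.stderr[n] / fit.estimates[n]
               for n in ("K_S", "k_2")}
        rel_ratio = fit.specificity_stderr / fit.specificity
        assert rel_ratio < 0.5 * rel["K_S"]
        assert rel_ratio < 0.5 * rel["k_2"]
        assert abs(fit.specificity - truth.specificity) < \
            3 * fit.specificity_stderr


class TestProfileSpecificity:
    def test_noiseless_interval_tight_and_bracketing(
            self, noiseless_fit, active_suite_noiseless_mod,
            active_curves_noiseless_mod):
        lo, hi = profile_specificity(noiseless_fit,
                                     active_suite_noiseless_mod,
                                     active_curves_noiseless_mod)
        spec = noiseless_fit.specificity
        assert lo <= spec <= hi
        assert (hi - lo) < 0.005 * spec


def _mock_fit(spec: float) -> FitResult:
    return FitResult(estimates={"K_S": 1e-5, "k_2": spec * 1e-5,
                                "K_P": 5e-7, "k_rep": 1e4},
                     stderr={}, cov=np.eye(4), free_names=("k_2",),
                     ssr=0.0, n_obs=10, residuals=[],
                     specificity=spec, specificity_stderr=0.0)


class TestSelectivityRatio:
    def test_identical_fits_give_unity(self):
        f = _mock_fit(1000.0)
        assert selectivity_ratio(f, f) == pytest.approx(1.0)

    @pytest.mark.parametrize("active,inactive,expected", [
        (13720.0, 220.0, 62.4),
        (32430.0, 410.0, 79.1),
    ])
    def test_measured_constants_reproduce_printed_folds(self, active,
                                                        inactive, expected):
        ratio = selectivity_ratio(_mock_fit(active), _mock_fit(inactive))
        assert ratio == pytest.approx(expected, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            selectivity_ratio(_mock_fit(100.0), _mock_fit(0.0))
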