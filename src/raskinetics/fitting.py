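"""Parameter estimation from progress curves.

Two layers:

* :func:`estimate_specificity_constant` fits a single RAS-free reporter
  curve to its closed-form single-exponential solution and returns the
  reporter specificity constant (kcat/KM).
* :func:`fit_global` fits a whole assay suite simultaneously to the
  cleavage mechanism, sharing ``K_S``, ``k_2``, ``K_P`` and ``k_rep``
  across curves, by multi-start nonlinear least squares in
  log-parameter space. The headline derived quantity is the specificity
  constant ``k_2 / K_S``, which progress curves identify much better
  than ``k_2`` or ``K_S`` individually when ``K_S`` lies above the
  titration range; :func:`profile_specificity` quantifies that with a
  profile-likelihood interval.

:func:`selectivity_ratio` compares two fits (active- vs inactive-RAS
suites) as the fold preference for the active conformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .mechanism import KineticParameters, ProgressCurve, simulate_progress
from .synthetic import ExperimentSuite

__all__ = [
    "FitFailure",
    "SpecificityEstimate",
    "FitResult",
    "estimate_specificity_constant",
    "fit_global",
    "profile_specificity",
    "selectivity_ratio",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
]

PARAM_NAMES = ("K_S", "k_2", "K_P", "k_rep")

#: Default box bounds (M, 1/s, M, 1/M/s); generous but physical.
DEFAULT_BOUNDS = {
    "K_S": (1e-8, 1e-2),
    "k_2": (1e-5, 1e3),
    "K_P": (1e-9, 1e-3),
    "k_rep": (1e1, 1e8),
}


class FitFailure(RuntimeError):
    """A curve carries no fittable signal or the optimizer failed."""


@dataclass(frozen=True)
class SpecificityEstimate:
    value: float            # 1/M/s
    stderr: float           # 1/M/s


@dataclass
class FitResult:
    """Outcome of a global mechanism fit."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    cov: np.ndarray                     # covariance of log free params
    free_names: tuple[str, ...]
    ssr: float
    n_obs: int
    residuals: list[np.ndarray]
    specificity: float                  # k_2 / K_S, 1/M/s
    specificity_stderr: float
    starts: list[dict] = field(default_factory=list)
    seed: int | None = None
    success: bool = True

    @property
    def dof(self) -> int:
        return self.n_obs - len(self.free_names)


def estimate_specificity_constant(curve: ProgressCurve,
                                  protease_total: float | None = None,
                                  reporter_total: float | None = None,
                                  fit_baseline: bool = False
                                  ) -> SpecificityEstimate:
    """Reporter kcat/KM from a RAS-free, r1-free progress curve.

    Fits ``AMC(t) = S0 * (1 - exp(-k * P_total * t))`` (plus an optional
    constant baseline) and returns ``k`` with its standard error. A flat
    curve — no signal beyond the noise floor — raises :class:`FitFailure`
    rather than returning a silent zero.
    """
    design = curve.design
    ptot = design.protease_total if protease_total is None else protease_total
    s0 = design.reporter_total if reporter_total is None else reporter_total
    t, y = curve.time, curve.amc

    floor = max(5.0 * curve.noise_sigma, 1e-9 * s0)
    if ptot <= 0 or (y.max() - y.min()) <= floor:
        raise FitFailure("progress curve is flat: no measurable turnover")

    # initial slope gives k * P * S0
    k0 = max((y[min(5, t.size - 1)] - y[0])
             / (s0 * ptot * max(t[min(5, t.size - 1)], 1e-12)), 1e-12)

    if fit_baseline:
        model = lambda t, logk, b: s0 * (1 - np.exp(-math.exp(logk) * ptot * t)) + b
        p0 = [math.log(k0), 0.0]
    else:
        model = lambda t, logk: s0 * (1 - np.exp(-math.exp(logk) * ptot * t))
        p0 = [math.log(k0)]
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitFailure(f"exponential fit did not converge: {exc}") from exc
    k = math.exp(popt[0])
    se = k * math.sqrt(max(pcov[0, 0], 0.0))
    return SpecificityEstimate(value=k, stderr=se)


def _curve_weights(curves: list[ProgressCurve]) -> list[float]:
    # residuals are expressed in signal-fraction units: known noise scale
    # when recorded, otherwise the curve's reporter total
    return [1.0 / (c.noise_sigma if c.noise_sigma > 0
                   else c.design.reporter_total) for c in curves]


def _suite_residuals(log_theta: np.ndarray, free_names: tuple[str, ...],
                     fixed: dict[str, float], curves: list[ProgressCurve],
                     weights: list[float]) -> np.ndarray:
    values = dict(fixed)
    values.update({n: math.exp(v) for n, v in zip(free_names, log_theta)})
    params = KineticParameters(**values)
    out = []
    for curve, w in zip(curves, weights):
        model, _ = simulate_progress(curve.design, params, trajectory=False)
        out.append((model.amc - curve.amc) * w)
    return np.concatenate(out)


def _initial_guess(suite: ExperimentSuite, curves: list[ProgressCurve],
                   fixed: dict[str, float]) -> dict[str, float]:
    """Staged starting point: pre-fit k_rep on the uninhibited curve."""
    guess = {"K_S": 5e-6, "k_2": 0.05, "K_P": 0.5e-6, "k_rep": 1e4}
    for curve in curves:
        if curve.design.ras_total == 0 and curve.design.r1_initial == 0:
            try:
                guess["k_rep"] = estimate_specificity_constant(curve).value
            except FitFailure:
                pass
            break
    ras_max = max(c.design.ras_total for c in curves)
    if ras_max > 0:
        guess["K_S"] = ras_max / 2.0
    guess.update(fixed)
    return guess


def fit_global(suite: ExperimentSuite, curves: list[ProgressCurve],
               init: dict[str, float] | None = None,
               bounds: dict[str, tuple[float, float]] | None = None,
               fixed: dict[str, float] | None = None,
               n_starts: int = 20, n_polish: int = 5,
               seed: int = 0) -> FitResult:
    """Global weighted least-squares fit of the mechanism to a suite.

    All free parameters are shared across curves and optimized in log
    space. ``n_starts`` starting points (the staged initial guess plus
    log-uniform draws within the bounds, drawn from ``seed``) are scored;
    the ``n_polish`` best are refined to full tolerance and the overall
    best is returned, with every start's outcome logged.

    ``fixed`` pins parameters (e.g. ``K_P`` determined from an
    independent r1-titration fit); the remaining names in
    :data:`PARAM_NAMES` are free.
    """
    if len(curves) != len(suite.designs):
        raise ValueError("curves must correspond one-to-one to suite designs")
    fixed = dict(fixed or {})
    free_names = tuple(n for n in PARAM_NAMES if n not in fixed)
    if not free_names:
        raise ValueError("at least one parameter must be free")
    bnds = dict(DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    lo = np.array([math.log(bnds[n][0]) for n in free_names])
    hi = np.array([math.log(bnds[n][1]) for n in free_names])

    weights = _curve_weights(curves)
    guess = _initial_guess(suite, curves, fixed)
    if init:
        guess.update(init)
    x_init = np.clip([math.log(guess[n]) for n in free_names], lo, hi)

    rng = np.random.default_rng(seed)
    starts = [x_init] + [rng.uniform(lo, hi) for _ in range(n_starts - 1)]

    def ssr_of(x: np.ndarray) -> float:
        try:
            return float(np.sum(_suite_residuals(
                x, free_names, fixed, curves, weights) ** 2))
        except Exception:
            return np.inf

    scored = sorted(range(len(starts)), key=lambda i: ssr_of(starts[i]))
    polish_idx = set(scored[:n_polish]) | {0}

    log: list[dict] = []
    best = None
    for i, x0 in enumerate(starts):
        entry = {"start": i, "ssr0": ssr_of(x0), "polished": i in polish_idx}
        if i in polish_idx:
            try:
                sol = least_squares(
                    _suite_residuals, x0, bounds=(lo, hi),
                    args=(free_names, fixed, curves, weights),
                    method="trf", x_scale="jac", max_nfev=400)
                entry.update(ssr=float(2 * sol.cost), converged=sol.success)
                if best is None or 2 * sol.cost < best["cost"]:
                    best = {"sol": sol, "cost": float(2 * sol.cost)}
            except Exception as exc:  # keep going; other starts may work
                entry.update(ssr=np.inf, converged=False, error=str(exc))
        log.append(entry)

    if best is None:
        raise FitFailure("no optimizer start converged; see per-start log")

    sol = best["sol"]
    log_est = sol.x
    estimates = dict(fixed)
    estimates.update({n: math.exp(v) for n, v in zip(free_names, log_est)})

    resid = _suite_residuals(log_est, free_names, fixed, curves, weights)
    n_obs = resid.size
    dof = max(n_obs - len(free_names), 1)
    s2 = float(resid @ resid) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov_log = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov_log = np.full((len(free_names),) * 2, np.nan)

    stderr = {n: 0.0 for n in fixed}
    for j, n in enumerate(free_names):
        stderr[n] = estimates[n] * math.sqrt(max(cov_log[j, j], 0.0))

    spec = estimates["k_2"] / estimates["K_S"]
    spec_se = _ratio_stderr(spec, cov_log, free_names)

    sizes = np.cumsum([0] + [c.amc.size for c in curves])
    per_curve = [resid[a:b] / w for a, b, w in
                 zip(sizes[:-1], sizes[1:], weights)]

    return FitResult(estimates=estimates, stderr=stderr, cov=cov_log,
                     free_names=free_names, ssr=float(resid @ resid),
                     n_obs=n_obs, residuals=per_curve, specificity=spec,
                     specificity_stderr=spec_se, starts=log, seed=seed)


def _ratio_stderr(spec: float, cov_log: np.ndarray,
                  free_names: tuple[str, ...]) -> float:
    """Delta-method standard error of k_2/K_S from the log covariance."""
    if not np.all(np.isfinite(cov_log)):
        return float("nan")
    g = np.zeros(len(free_names))
    for j, n in enumerate(free_names):
        if n == "k_2":
            g[j] = 1.0
        elif n == "K_S":
            g[j] = -1.0
    var_log = float(g @ cov_log @ g)
    return spec * math.sqrt(max(var_log, 0.0))


def profile_specificity(fit: FitResult, suite: ExperimentSuite,
                        curves: list[ProgressCurve],
                        grid: np.ndarray | None = None,
                        level: float = 0.95,
                        max_span: float = 10.0) -> tuple[float, float]:
    """Profile-likelihood interval for the specificity constant k_2/K_S.

    The model is reparametrized as (ratio, K_S, ...): at each grid value
    of the ratio, ``k_2 = ratio * K_S`` is constrained and the remaining
    free parameters are re-optimized (warm-started from the neighbouring
    grid point). The interval is where the profiled SSR stays below
    ``SSR_min * (1 + F(1, dof; level) / dof)``. If the profile never
    crosses the threshold within ``max_span``-fold of the estimate, the
    corresponding side is reported at the span edge (practically
    unbounded in that direction).
    """
    spec_hat = fit.specificity
    fixed_base = {n: fit.estimates[n] for n in PARAM_NAMES
                  if n not in fit.free_names}
    nuisance = tuple(n for n in fit.free_names if n != "k_2")
    weights = _curve_weights(curves)
    dof = max(fit.dof, 1)
    threshold = fit.ssr * (1.0 + stats.f.ppf(level, 1, dof) / dof)
    # guard against an exactly-zero noiseless SSR
    threshold = max(threshold, fit.ssr + 1e-12 * (fit.ssr + 1e-300))

    lo_b = np.array([math.log(DEFAULT_BOUNDS[n][0]) for n in nuisance])
    hi_b = np.array([math.log(DEFAULT_BOUNDS[n][1]) for n in nuisance])

    def profiled_ssr(ratio: float, x0: np.ndarray) -> tuple[float, np.ndarray]:
        def resid(x: np.ndarray) -> np.ndarray:
            vals = dict(fixed_base)
            vals.update({n: math.exp(v) for n, v in zip(nuisance, x)})
            vals["k_2"] = ratio * vals["K_S"]
            params = KineticParameters(**vals)
            out = []
            for curve, w in zip(curves, weights):
                model, _ = simulate_progress(curve.design, params,
                                             trajectory=False)
                out.append((model.amc - curve.amc) * w)
            return np.concatenate(out)

        if nuisance:
            sol = least_squares(resid, np.clip(x0, lo_b, hi_b),
                                bounds=(lo_b, hi_b), method="trf",
                                x_scale="jac", max_nfev=200)
            return float(2 * sol.cost), sol.x
        r = resid(x0)
        return float(r @ r), x0

    x_hat = np.array([math.log(fit.estimates[n]) for n in nuisance])

    # initial step from the Wald standard error, then bracket + bisect
    rel_se = fit.specificity_stderr / spec_hat \
        if np.isfinite(fit.specificity_stderr) and fit.specificity_stderr > 0 \
        else 1e-3
    step0 = min(max(1.0 + 2.0 * rel_se, 1.0001), 1.5)

    def scan(direction: int) -> float:
        x0 = x_hat.copy()
        inside, outside = spec_hat, None
        step = step0
        while abs(math.log(inside / spec_hat)) < math.log(max_span):
            trial = inside * step if direction > 0 else inside / step
            ssr, x0 = profiled_ssr(trial, x0)
            if ssr > threshold:
                outside = trial
                break
            inside = trial
            step = min(step ** 2, 2.0)
        if outside is None:
            return inside  # edge of span: practically unbounded
        for _ in range(30):
            mid = math.sqrt(inside * outside)
            ssr, x0 = profiled_ssr(mid, x0)
            if ssr > threshold:
                outside = mid
            else:
                inside = mid
            if abs(math.log(outside / inside)) < 1e-5:
                break
        return math.sqrt(inside * outside)

    if grid is not None:
        ssrs = []
        x0 = x_hat.copy()
        for r in np.sort(np.asarray(grid, dtype=float)):
            s, x0 = profiled_ssr(r, x0)
            ssrs.append(s)
        inside = np.asarray(ssrs) <= threshold
        if not inside.any():
            return (spec_hat, spec_hat)
        g = np.sort(np.asarray(grid, dtype=float))
        return float(g[inside].min()), float(g[inside].max())

    return scan(-1), scan(+1)


def selectivity_ratio(fit_active: FitResult, fit_inactive: FitResult
                      ) -> float:
    """Fold preference for active RAS: (k_2/K_S)_active / (k_2/K_S)_inactive."""
    denom = fit_inactive.specificity
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("inactive-form specificity must be positive and finite")
    return fit_active.specificity / denom
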