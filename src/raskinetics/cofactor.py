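"""Cofactor activation of active-site-deleted proteases.

The engineered proteases carry a catalytic-residue deletion (D32G
rescued by nitrite, H64G rescued by imidazole), so their specificity
constant toward the cognate reporter rises with cofactor concentration
from a basal value ``v0`` to a saturating ``v_max`` with half-activation
at ``K_act``. A Hill exponent ``h`` (default 1, i.e. hyperbolic) is
exposed because the activation curves are empirical.

:func:`two_state_linkage` formalizes the verbal conformational-selection
model of activation — an inactive/active pre-equilibrium ``L`` shifted
by cofactor binding (to the active form only) and by cognate sub-site
contacts (Boltzmann factor ``delta_g_substrate``). It is an
illustrative model, not fitted to any measured dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ActivationParameters",
    "ActivationFit",
    "activation_value",
    "fit_activation",
    "cognate_fold",
    "two_state_linkage",
]


@dataclass(frozen=True)
class ActivationParameters:
    """Saturating activation curve: v(c) = v0 + (v_max − v0)·cʰ/(K_actʰ + cʰ)."""

    v0: float        # basal specificity constant, 1/M/s
    v_max: float     # saturating specificity constant, 1/M/s
    K_act: float     # half-activation cofactor concentration, M
    h: float = 1.0   # cooperativity exponent

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v0) and self.v0 >= 0):
            raise ValueError("v0 must be finite and >= 0")
        if not (np.isfinite(self.v_max) and self.v_max >= self.v0):
            raise ValueError("v_max must be finite and >= v0")
        if not (np.isfinite(self.K_act) and self.K_act > 0):
            raise ValueError("K_act must be > 0")
        if not (np.isfinite(self.h) and self.h > 0):
            raise ValueError("h must be > 0")


@dataclass(frozen=True)
class ActivationFit:
    params: ActivationParameters
    stderr: dict[str, float]
    ssr: float
    ill_conditioned: bool = False
    message: str = ""


def activation_value(c, p: ActivationParameters):
    """Specificity constant at cofactor concentration ``c`` (scalar or array)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("cofactor concentration must be finite and >= 0")
    ch = np.power(c, p.h)
    out = p.v0 + (p.v_max - p.v0) * ch / (p.K_act ** p.h + ch)
    return float(out) if out.ndim == 0 else out


def fit_activation(points, h: float | None = None,
                   fit_v0: bool = True) -> ActivationFit:
    """Least-squares fit of the activation curve to (cofactor, kcat/KM) data.

    ``points`` is an iterable of (cofactor molar, specificity constant)
    pairs; at least 4 points are required. If the data do not bracket
    ``K_act`` (flat within measurement scatter, or all points on one
    side of the fitted midpoint) the result is flagged
    ``ill_conditioned`` rather than failing silently.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (cofactor, value) points")
    c, v = arr[:, 0], arr[:, 1]
    if np.any(c < 0):
        raise ValueError("cofactor concentrations must be >= 0")

    span = v.max() - v.min()
    vscale = max(v.max(), 1e-300)
    kact0 = np.median(c[c > 0]) if np.any(c > 0) else 1e-3

    free_h = h is None

    def model(c, *theta):
        v0 = theta[0] if fit_v0 else 0.0
        off = 1 if fit_v0 else 0
        vmax, log_kact = theta[off], theta[off + 1]
        hh = theta[off + 2] if free_h else (h or 1.0)
        ch = np.power(c, hh)
        return v0 + (vmax - v0) * ch / (math.exp(log_kact) ** hh + ch)

    p0 = ([v.min()] if fit_v0 else []) + [v.max(), math.log(kact0)] \
        + ([1.0] if free_h else [])
    names = (["v0"] if fit_v0 else []) + ["v_max", "K_act"] \
        + (["h"] if free_h else [])
    try:
        popt, pcov = curve_fit(model, c, v, p0=p0, maxfev=20000)
    except RuntimeError:
        return ActivationFit(
            params=ActivationParameters(v0=float(v.min()), v_max=float(v.max()),
                                        K_act=kact0, h=h or 1.0),
            stderr={n: float("nan") for n in names}, ssr=float("inf"),
            ill_conditioned=True, message="optimizer did not converge")

    resid = model(c, *popt) - v
    ssr = float(resid @ resid)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))

    off = 1 if fit_v0 else 0
    v0_hat = float(popt[0]) if fit_v0 else 0.0
    vmax_hat = float(popt[off])
    kact_hat = float(math.exp(popt[off + 1]))
    h_hat = float(popt[off + 2]) if free_h else float(h or 1.0)

    flat = span <= 1e-6 * vscale
    one_sided = (c.max() < kact_hat) or (np.min(c[c > 0], initial=np.inf)
                                         > kact_hat)
    msg = ""
    if flat:
        msg = "flat data: K_act unidentifiable"
    elif one_sided:
        msg = "all cofactor points on one side of fitted K_act"

    # clamp pathological flat-curve output into a valid parameter set
    v0_hat = min(max(v0_hat, 0.0), vmax_hat) if vmax_hat >= 0 else 0.0
    stderr = {}
    for n, s, val in zip(names, se,
                         [v0_hat] * fit_v0 + [vmax_hat, kact_hat]
                         + [h_hat] * free_h):
        stderr[n] = float(s * kact_hat) if n == "K_act" else float(s)

    return ActivationFit(
        params=ActivationParameters(v0=v0_hat, v_max=max(vmax_hat, v0_hat),
                                    K_act=kact_hat, h=h_hat),
        stderr=stderr, ssr=ssr,
        ill_conditioned=flat or one_sided, message=msg)


def cognate_fold(p_cognate: ActivationParameters,
                 p_noncognate: ActivationParameters, c: float) -> float:
    """Cognate / non-cognate specificity ratio at cofactor concentration c."""
    denom = activation_value(c, p_noncognate)
    if denom == 0:
        raise ZeroDivisionError("non-cognate activity is zero at this cofactor")
    return activation_value(c, p_cognate) / denom


def two_state_linkage(L: float, K_act_active: float,
                      delta_g_substrate: float, c: float) -> float:
    """Fraction of enzyme in the activatable conformation.

    A two-state enzyme (inactive/active equilibrium constant ``L``
    favouring inactive when L > 1) is pulled toward the active state by
    cofactor binding (dissociation constant ``K_act_active``, active
    state only) and by cognate substrate contacts (Boltzmann factor
    ``delta_g_substrate`` >= 1 for stabilization):

        f = (1 + c/K_act)·δ / (L + (1 + c/K_act)·δ)
    """
    if not (np.isfinite(L) and L > 0):
        raise ValueError("L must be > 0")
    if not (np.isfinite(K_act_active) and K_act_active > 0):
        raise ValueError("K_act_active must be > 0")
    if not (np.isfinite(delta_g_substrate) and delta_g_substrate > 0):
        raise ValueError("delta_g_substrate must be > 0")
    if not (np.isfinite(c) and c >= 0):
        raise ValueError("c must be finite and >= 0")
    w = (1.0 + c / K_act_active) * delta_g_substrate
    return w / (L + w)
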