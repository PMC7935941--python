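"""Reaction mechanism for conformation-selective RAS proteolysis.

The minimal mechanism couples two competing processes on one protease:

* reversible binding of intact RAS (``R + P <-> RP``, dissociation constant
  ``K_S``) followed by irreversible acylation (``RP -> Pr1 + r2`` at rate
  ``k_2``), with the N-terminal fragment r1 remaining bound as a reversible
  product complex (``Pr1 <-> P + r1``, dissociation constant ``K_P``);
* first-order consumption of a fluorogenic reporter peptide
  (QEEYSAM-AMC) by free protease at a specificity constant ``k_rep``
  (kcat/KM), releasing the measured AMC fluorophore.

RAS and the r1 fragment are therefore seen in the data as competitive
inhibitors of reporter turnover: early in a progress curve intact RAS
dominates the inhibition, and as cleavage proceeds the accumulating r1
product takes over.

Two simulation modes are provided. ``rapid_equilibrium`` treats both
binding steps as instantaneous equilibria, so only ``K_S``, ``k_2`` and
``K_P`` matter — this matches what progress curves can identify. The
``mass_action`` mode expands each equilibrium with an explicit association
rate ``k_on`` (off-rate ``k_on * K``) and serves as an independent check:
the two modes converge as ``k_on`` grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SPECIES",
    "KineticParameters",
    "AssayDesign",
    "SpeciesState",
    "ProgressCurve",
    "free_protease",
    "equilibrium_state",
    "mechanism_rhs",
    "simulate_progress",
    "trajectory_to_frame",
]

Mode = Literal["rapid_equilibrium", "mass_action"]

#: Species tracked in a full state, in canonical order.
SPECIES = ("R", "P", "RP", "Pr1", "S", "r1", "r2", "AMC")


def _require_finite_nonneg(name: str, value: float, strict: bool = False) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Rate and equilibrium constants of the cleavage mechanism.

    Parameters
    ----------
    K_S : float
        Dissociation constant of the protease·RAS complex (M).
    k_2 : float
        Acylation rate constant, the first chemical step of RAS cleavage
        (1/s).
    K_P : float
        Dissociation constant of the protease·r1 product complex (M).
    k_rep : float
        Specificity constant (kcat/KM) for reporter-peptide cleavage
        (1/M/s). The reporter operates far below saturation, so its flux
        is ``k_rep * [P_free] * [S]``.
    k_on : float
        Association rate constant used only to expand the equilibria into
        mass action (1/M/s); off-rates are ``k_on * K_S`` and
        ``k_on * K_P``.
    """

    K_S: float
    k_2: float
    K_P: float
    k_rep: float
    k_on: float = 1e7

    def __post_init__(self) -> None:
        for name in ("K_S", "k_2", "K_P", "k_rep", "k_on"):
            _require_finite_nonneg(name, getattr(self, name), strict=True)

    @property
    def specificity(self) -> float:
        """Specificity constant k_2 / K_S toward intact RAS (1/M/s)."""
        return self.k_2 / self.K_S

    def with_k_on(self, k_on: float) -> "KineticParameters":
        return replace(self, k_on=k_on)


@dataclass(frozen=True)
class AssayDesign:
    """Initial conditions and observation grid for one progress curve."""

    protease_total: float
    ras_total: float
    reporter_total: float
    time_grid: np.ndarray
    ras_form: Literal["active", "inactive"] = "active"
    r1_initial: float = 0.0
    cofactor_id: Literal["imidazole", "nitrite", "none"] = "none"
    cofactor_conc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("protease_total", "ras_total", "reporter_total",
                     "r1_initial", "cofactor_conc"):
            _require_finite_nonneg(name, getattr(self, name))
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("time_grid must be a 1-D array of >= 2 times")
        if grid[0] != 0.0:
            raise ValueError("time_grid must start at 0")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("time_grid must be strictly increasing")
        object.__setattr__(self, "time_grid", grid)


@dataclass(frozen=True)
class SpeciesState:
    """Full concentration state (M): intact RAS, protease and complexes,
    reporter, cleavage fragments and released AMC."""

    R: float
    P: float
    RP: float
    Pr1: float
    S: float
    r1: float
    r2: float
    AMC: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        return cls(**dict(zip(SPECIES, np.asarray(y, dtype=float))))


@dataclass
class ProgressCurve:
    """Time course of released AMC for one assay design."""

    time: np.ndarray
    amc: np.ndarray
    design: AssayDesign
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amc = np.asarray(self.amc, dtype=float)
        if self.time.shape != self.amc.shape:
            raise ValueError("time and amc must have equal length")


def free_protease(protease_total: float, ras_intact_total: float,
                  r1_total: float, K_S: float, K_P: float) -> float:
    """Free protease concentration under rapid-equilibrium partitioning.

    Solves the conservation equation

        P * (1 + Rt / (K_S + P) + r1t / (K_P + P)) = protease_total

    for ``P`` by bracketed root-finding on ``[0, protease_total]``. The
    left side is strictly increasing in ``P``, so the root is unique.
    """
    for name, v in (("protease_total", protease_total),
                    ("ras_intact_total", ras_intact_total),
                    ("r1_total", r1_total)):
        _require_finite_nonneg(name, v)
    _require_finite_nonneg("K_S", K_S, strict=True)
    _require_finite_nonneg("K_P", K_P, strict=True)

    if protease_total == 0.0:
        return 0.0
    if ras_intact_total == 0.0 and r1_total == 0.0:
        return protease_total

    def residual(P: float) -> float:
        return P * (1.0 + ras_intact_total / (K_S + P)
                    + r1_total / (K_P + P)) - protease_total

    # residual(0) = -protease_total < 0; residual(Ptot) >= 0
    return brentq(residual, 0.0, protease_total, xtol=1e-30, rtol=1e-14,
                  maxiter=200)


def equilibrium_state(intact_ras: float, r1_total: float, S: float,
                      AMC: float, protease_total: float,
                      params: KineticParameters) -> SpeciesState:
    """Expand pool totals into a full state via equilibrium partitioning."""
    P = free_protease(protease_total, intact_ras, r1_total,
                      params.K_S, params.K_P)
    RP = P * intact_ras / (params.K_S + P)
    Pr1 = P * r1_total / (params.K_P + P)
    return SpeciesState(R=intact_ras - RP, P=P, RP=RP, Pr1=Pr1, S=S,
                        r1=r1_total - Pr1, r2=r1_total, AMC=AMC)


def mechanism_rhs(state: SpeciesState, params: KineticParameters,
                  design: AssayDesign, mode: Mode = "rapid_equilibrium"
                  ) -> SpeciesState:
    """Time derivatives of the species state under the chosen mode.

    In ``rapid_equilibrium`` mode the binding steps are algebraic
    constraints, so derivatives are reported on the pools: cleavage flux
    ``k_2 * [RP]`` leaves the intact-RAS pool (attributed to ``R``) and
    enters the product pools (``r1`` and ``r2``); the split between free
    and complexed species within a pool is held by the equilibrium, so
    ``dP = dRP = dPr1 = 0``. In ``mass_action`` mode every step carries
    an explicit rate and the full 8-species derivative is returned.
    """
    if mode == "rapid_equilibrium":
        intact = state.R + state.RP
        r1_total = state.r1 + state.Pr1
        P = free_protease(design.protease_total, intact, r1_total,
                          params.K_S, params.K_P)
        RP = P * intact / (params.K_S + P)
        cleave = params.k_2 * RP
        rep = params.k_rep * P * state.S
        return SpeciesState(R=-cleave, P=0.0, RP=0.0, Pr1=0.0,
                            S=-rep, r1=cleave, r2=cleave, AMC=rep)
    if mode == "mass_action":
        kon = params.k_on
        v_bind = kon * (state.R * state.P - params.K_S * state.RP)
        v_cat = params.k_2 * state.RP
        v_rel = kon * (params.K_P * state.Pr1 - state.r1 * state.P)
        rep = params.k_rep * state.P * state.S
        return SpeciesState(
            R=-v_bind,
            P=-v_bind + v_rel,
            RP=v_bind - v_cat,
            Pr1=v_cat - v_rel,
            S=-rep,
            r1=v_rel,
            r2=v_cat,
            AMC=rep,
        )
    raise ValueError(f"unknown mode {mode!r}")


def _reduced_rhs(t: float, y: np.ndarray, params: KineticParameters,
                 design: AssayDesign) -> list[float]:
    # y = [intact RAS pool, uncleaved reporter]
    intact = max(y[0], 0.0)
    r1_total = design.ras_total + design.r1_initial - intact
    P = free_protease(design.protease_total, intact, max(r1_total, 0.0),
                      params.K_S, params.K_P)
    RP = P * intact / (params.K_S + P)
    return [-params.k_2 * RP, -params.k_rep * P * max(y[1], 0.0)]


def _mass_action_rhs(t: float, y: np.ndarray, params: KineticParameters
                     ) -> np.ndarray:
    R, P, RP, Pr1, S, r1, r2, AMC = y
    kon = params.k_on
    v_bind = kon * (R * P - params.K_S * RP)
    v_cat = params.k_2 * RP
    v_rel = kon * (params.K_P * Pr1 - r1 * P)  # > 0 releases P and r1
    rep = params.k_rep * P * S
    return np.array([
        -v_bind,           # R
        -v_bind + v_rel,   # P
        v_bind - v_cat,    # RP
        v_cat - v_rel,     # Pr1
        -rep,              # S
        v_rel,             # r1
        v_cat,             # r2
        rep,               # AMC
    ])


def simulate_progress(design: AssayDesign, params: KineticParameters,
                      mode: Mode = "rapid_equilibrium",
                      rtol: float = 1e-10, atol: float = 1e-14,
                      trajectory: bool = True
                      ) -> tuple[ProgressCurve, pd.DataFrame | None]:
    """Simulate one progress curve.

    Returns the AMC progress curve on ``design.time_grid`` together with
    the full species trajectory (a DataFrame with a ``time_s`` column and
    one column per species, molar); pass ``trajectory=False`` to skip
    building the species table (the fitting hot path does). Negative
    round-off below the solver tolerance is clipped at zero.

    The absolute tolerance is tightened automatically when the smallest
    conserved pool sits far below the default scale, so conservation
    sums stay within 1e-6 relative drift even for nanomolar totals.
    """
    totals = [v for v in (design.protease_total,
                          design.ras_total + design.r1_initial,
                          design.reporter_total) if v > 0]
    if totals:
        atol = min(atol, 1e-8 * min(totals))
    t = design.time_grid
    if mode == "rapid_equilibrium":
        y0 = [design.ras_total, design.reporter_total]
        sol = solve_ivp(_reduced_rhs, (t[0], t[-1]), y0, t_eval=t,
                        args=(params, design), method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"progress-curve integration failed: {sol.message}")
        intact = np.clip(sol.y[0], 0.0, design.ras_total)
        S = np.clip(sol.y[1], 0.0, design.reporter_total)
        amc = design.reporter_total - S
        if not trajectory:
            curve = ProgressCurve(time=t, amc=amc, design=design)
            return curve, None
        rows = [equilibrium_state(
                    intact[i],
                    max(design.ras_total + design.r1_initial - intact[i], 0.0),
                    S[i], amc[i], design.protease_total, params)
                for i in range(t.size)]
        # r2 differs from the r1 pool when r1 is pre-loaded
        traj = pd.DataFrame([r.as_array() for r in rows], columns=SPECIES)
        traj["r2"] = (design.ras_total - intact)
    elif mode == "mass_action":
        # start from the equilibrated state so the fast binding transient
        # does not dominate the error control
        y0 = equilibrium_state(design.ras_total, design.r1_initial,
                               design.reporter_total, 0.0,
                               design.protease_total, params).as_array()
        y0[6] = 0.0  # no r2 present initially even if r1 is pre-loaded
        sol = solve_ivp(_mass_action_rhs, (t[0], t[-1]), y0, t_eval=t,
                        args=(params,), method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"progress-curve integration failed: {sol.message}")
        traj = pd.DataFrame(np.clip(sol.y.T, 0.0, None), columns=SPECIES)
        amc = traj["AMC"].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    traj.insert(0, "time_s", t)
    curve = ProgressCurve(time=t, amc=np.asarray(amc, dtype=float),
                          design=design)
    return curve, traj


def trajectory_to_frame(curve_id: str, traj: pd.DataFrame) -> pd.DataFrame:
    """Tag a trajectory with a curve identifier for CSV export."""
    out = traj.copy()
    out.insert(0, "curve_id", curve_id)
    return out
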