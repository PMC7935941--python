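# Methods

## Mechanism and assumptions

The cleavage mechanism treats intact RAS (R) as a substrate whose
binding to the protease (P) is a rapid equilibrium with dissociation
constant `K_S`, followed by irreversible acylation at rate `k_2` that
converts RP into a protease·r1 product complex plus the free C-terminal
fragment r2. The r1 fragment re-binds with dissociation constant `K_P`
and acts as a competitive product inhibitor; r2 is assumed inert (the
mechanism has no r2 re-binding step, and cleaved RAS fragments are
disordered, giving r2 no structured epitope for the substrate groove).
The fluorogenic reporter is consumed in the first-order regime,
`d[AMC]/dt = k_rep·[P]·[S]`, with no explicit protease·reporter
complex: at 1 µM reporter the enzyme is far below reporter saturation,
which is why the reporter is characterized by a single specificity
constant rather than separate k_cat and K_M. The protease·r1 complex
lumps together the non-covalent product complex and the acyl-enzyme
adduct seen crystallographically; progress curves cannot distinguish
them, so one equilibrium constant carries both.

Two simulation modes:

* **rapid_equilibrium** (default). Free protease is the root of
  `P·(1 + Rt/(K_S+P) + r1t/(K_P+P)) = P_total`, solved by bracketed
  Brent iteration on `[0, P_total]` (relative tolerance 1e-14). The
  reporter does not feed back on the RAS subsystem, so the system
  reduces exactly to a 2-state ODE (intact-RAS pool, uncleaved
  reporter); complexed species are reconstructed algebraically for
  trajectory output. Only `K_S`, `k_2`, `K_P`, `k_rep` enter — the set
  progress curves can identify.
* **mass_action**. Binding steps expanded with an association rate
  `k_on` (default 1e7 M⁻¹s⁻¹; off-rates `k_on·K`). Used as an
  independent oracle: trajectories converge on the rapid-equilibrium
  ones as `k_on → ∞` (within 0.5 % of the reporter total at
  1e9 M⁻¹s⁻¹ on all titration designs), and as a stiffness check.

Integration uses LSODA with rtol 1e-10 and atol 1e-14; the atol is
additionally scaled down to 1e-8 × the smallest conserved pool so
conservation sums drift by < 1e-6 relative even with nanomolar totals.
These are tighter than a progress-curve fit strictly needs, but they
let the simulator meet its closed-form oracle (the RAS-free
single-exponential limit) to 1e-6 relative, and the integrations are
cheap (~1 ms per curve). Negative round-off is clipped at zero on
output only.

## Synthetic assays

No raw traces are deposited, so the generator emulates the two
experimental series with their published designs:

* **RAS titration** — 100 nM protease, 1 µM QEEYSAM-AMC, RAS at
  {0, 1.25, 2.5, 5, 10, 20} µM (a doubling grid across the published
  0–20 µM range, chosen for K_S identifiability), in the variant's
  cofactor context (1 mM imidazole or 1 mM nitrite).
* **r1 inhibition titration** — no intact RAS, purified r1 fragment on
  a 6-point log grid from 50 nM to 3.3 µM crossed with reporter at
  {0.1, 0.5, 1} µM (18 curves). This pins `K_P` independently.

The observation window is auto-scaled from the truth parameters:
`t_end = ln(10)/(k_rep·P_total)` (≈ 2,300 s at the defaults), so the
uninhibited curve reaches ~90 % completion — comfortably past the 50 %
reporter consumption the titration design requires — sampled at 201
evenly spaced points. Noise is additive, homoscedastic Gaussian with
σ = 1 % of the curve's reporter total (typical stopped-flow
fluorescence precision), with per-curve seeds spawned deterministically
from the suite seed; suites regenerate bit-identically. Real traces
have instrument dead time, photobleaching, inner-filter effects and
correlated drift that this generator deliberately omits; passing
recovery tests therefore demonstrate estimator correctness and
identifiability under the stated noise model, not robustness to every
instrumental artifact.

### Reference truth constants

Only the specificity constants k_2/K_S are published (13,720 / 220
M⁻¹s⁻¹ for the imidazole-dependent protease toward active/inactive
RAS; 32,430 / 410 for the nitrite-dependent one); the individual
constants behind them are not. The generator therefore fixes, once:
`K_S` = 10 µM (active) and 20 µM (inactive) — binding weak enough that
no titration point saturates, consistent with inhibition rising across
the whole 0–20 µM series; `K_P` = 0.5 µM — inside the 50 nM–3.3 µM r1
titration window, which is only an informative design if it brackets
`K_P`; `k_rep` = 1e4 M⁻¹s⁻¹ — a mid-range value for engineered
subtilisins on cognate AMC substrates; and `k_2` derived from the
published ratio. Recovery targets are stated on the ratio, which is the
published quantity and the well-identified one.

## Global fitting

Weighted least squares over all curves of a suite simultaneously, with
`K_S`, `k_2`, `K_P`, `k_rep` shared across curves and optimized in log
space (TRF with box bounds spanning several decades around physical
values). Residuals are scaled per curve by the known noise sigma (or
the reporter total when noiseless), which reduces to unit weights in
signal-fraction units for the homoscedastic default. The staged
strategy mirrors the experimental logic: `k_rep` is pre-fit on the
RAS-free curve via the closed-form exponential, `K_P` is fitted from
the r1 titration (where `K_S` and `k_2` do not enter) and then shared
with the RAS-titration fits, and all released parameters are refined
globally. 20 starting points (the staged guess plus log-uniform draws
from a fixed seed) are scored by initial SSR; the best five are
polished to full tolerance and every start's outcome is logged. Since
only the best polished optimum is kept, the reported objective is
monotone over accepted candidates by construction.

Uncertainties come from the local covariance in log space (delta
method for linear-scale standard errors and for the ratio k_2/K_S).
`profile_specificity` additionally profiles the ratio: it
reparametrizes to (k_2/K_S, K_S, …), re-optimizes the nuisance
parameters on a bracket-and-bisect grid around the estimate, and
reports the interval where SSR ≤ SSR_min·(1 + F(1, dof; 0.95)/dof).
When the profile never crosses the threshold within a 10-fold span the
interval is reported at the span edge (practically unbounded — the
expected outcome for `k_2` or `K_S` individually when `K_S` lies above
the titration range).

Measured behaviour of the estimator under the default conditions (from
the seeded recovery studies in the test suite): noiseless fits recover
all four parameters to optimizer precision; at 1 % noise the recovered
k_2/K_S is unbiased with a relative standard error of ~1 % for the
active forms and ~4 % for the inactive forms, whose slow cleavage makes
the ratio intrinsically harder to pin down within the ~2,300-s window.
Individual seeds can therefore land outside a 5 % band on the inactive
ratio (a ±1.5 σ event) while remaining statistically consistent with
truth — the fitted standard errors, which match the across-seed
scatter, are the honest uncertainty statement.

## Cofactor activation

Activity versus cofactor concentration is modelled as a saturating
Hill curve `v(c) = v0 + (v_max − v0)·cʰ/(K_actʰ + cʰ)` with h = 1 by
default — the published activation data are graphical and given
without an equation, so the hyperbolic form is the package's choice and
h is exposed. `two_state_linkage` formalizes the verbal
conformational-selection model (inactive/active pre-equilibrium L,
cofactor binding to the active state, cognate sub-site contacts as a
Boltzmann factor δ): `f = (1 + c/K_act)·δ / (L + (1 + c/K_act)·δ)`.
It is illustrative algebra, not fitted to any measured dataset, and is
flagged as such in its docstring.

## Cellular turnover

A three-pool linear ODE (active A, inactive I, cleaved C) with
piecewise-constant synthesis and protease concentration:
`dA/dt = s(t) − k_h·A − v_a·P(t)·A`, `dI/dt = k_h·A − v_i·P(t)·I`,
`dC/dt = v_a·P(t)·A + v_i·P(t)·I`, in hour units (specificity
constants converted from M⁻¹s⁻¹). GTP hydrolysis `k_h` defaults to
1 h⁻¹; the GDP form is assumed not to re-exchange (no exchange factors
in *E. coli*). In-cell synthesis rates and protease levels are not
measured, so the packaged scenario (synthesis 1 µM/h over 0–41 h,
35 nM protease from 17 h, 60-fold preference) is illustrative: it was
computed forward from the mechanism to show the qualitative signature
— > 50 % of RAS cleaved by 41 h while a > 97 %-inactive intact pool
persists — and every quantitative claim from this module is framed as
a property of the mechanism, not a reproduction of data. Integration
is split exactly at the synthesis-stop and protease-onset breakpoints.

## Numerical and design notes

* Internal units are molar and seconds everywhere except the turnover
  module (hours, documented conversion).
* `free_protease` input validation rejects negative or non-finite
  concentrations; the ODE right-hand side clamps round-off negatives
  before partitioning.
* In rapid-equilibrium mode the species-level derivative is reported on
  pools (intact RAS, cleaved products, reporter, AMC) with the
  free/complexed split held by the algebraic equilibrium — the split's
  own rate of change is not a mechanism rate and is deliberately not
  attributed to any single step.
* The mass-action initial state is pre-equilibrated so the fast binding
  transient does not dominate error control.
* Problem sizes in the packaged studies (6-curve titrations at 201
  points, 18-curve r1 titrations, 20 optimizer starts with 5 polished)
  keep a full two-variant recovery under a minute each while leaving
  estimates at the information bound of the design.

## Known limitations

* Deacylation/re-acylation microsteps, cofactor-binding kinetics inside
  the cleavage mechanism, and heteroscedastic error models are out of
  scope; cofactor effects enter only through parameter values.
* The Gaussian noise model understates real instrumental structure (see
  above), so recovery percentages quoted here should not be read as
  expected accuracy on real stopped-flow data.
* The two-state linkage and turnover modules are deliberately
  illustrative formalizations of verbal models; their parameters are
  not identifiable from any packaged dataset.
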