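"""Synthetic assay suites emulating the RAS-protease kinetic experiments.

No raw fluorescence traces are deposited for these assays, so every
downstream stage (global fitting, selectivity analysis, the recovery
studies) runs on synthetic data generated here. Two suite builders mirror
the two experimental series:

* a RAS titration — 100 nM protease, 1 µM QEEYSAM-AMC reporter, RAS
  (active GMPPNP- or inactive GDP-loaded) titrated 0–20 µM — from which
  ``K_S`` and ``k_2`` are identified;
* an r1-fragment inhibition titration — purified N-terminal cleavage
  product (50 nM–3.3 µM) against 0.1/0.5/1 µM reporter with no intact
  RAS — from which ``K_P`` is identified independently.

Reference ("truth") parameter sets for the four protease·RAS
combinations are provided with specificity constants matching the
measured values for the imidazole-dependent protease (13,720 and
220 M⁻¹s⁻¹ toward active and inactive RAS) and the nitrite-dependent
protease (32,430 and 410 M⁻¹s⁻¹). The individual constants behind each
ratio are not published; the defaults place K_S above the titration
range (10–20 µM) and K_P inside the r1 range (0.5 µM), see docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanism import (AssayDesign, KineticParameters, ProgressCurve,
                        simulate_progress)

__all__ = [
    "NoiseModel",
    "ExperimentSuite",
    "REFERENCE_TRUTH",
    "default_time_grid",
    "build_ras_titration_suite",
    "build_kp_titration_suite",
    "simulate_suite",
    "add_noise",
    "substrate_conc_from_absorbance",
]

#: RAS concentrations of the titration series (M): 0–20 µM doubling grid.
RAS_TITRATION_M = (0.0, 1.25e-6, 2.5e-6, 5e-6, 10e-6, 20e-6)

#: r1-fragment grid bounds (M) and reporter levels (M) of the K_P assay.
R1_MIN_M, R1_MAX_M = 50e-9, 3.3e-6
KP_REPORTER_M = (0.1e-6, 0.5e-6, 1.0e-6)

PROTEASE_TOTAL_M = 100e-9
REPORTER_TOTAL_M = 1e-6

#: Reference truth sets keyed by (protease variant, RAS nucleotide form).
#: k_2 is derived from the measured specificity constant k_2/K_S.
REFERENCE_TRUTH: dict[tuple[str, str], KineticParameters] = {
    ("I", "active"): KineticParameters(K_S=10e-6, k_2=13720 * 10e-6,
                                       K_P=0.5e-6, k_rep=1e4),
    ("I", "inactive"): KineticParameters(K_S=20e-6, k_2=220 * 20e-6,
                                         K_P=0.5e-6, k_rep=1e4),
    ("N", "active"): KineticParameters(K_S=10e-6, k_2=32430 * 10e-6,
                                       K_P=0.5e-6, k_rep=1e4),
    ("N", "inactive"): KineticParameters(K_S=20e-6, k_2=410 * 20e-6,
                                         K_P=0.5e-6, k_rep=1e4),
}

COFACTOR_FOR_VARIANT = {"I": ("imidazole", 1e-3), "N": ("nitrite", 1e-3)}


@dataclass(frozen=True)
class NoiseModel:
    """Additive homoscedastic Gaussian noise on the AMC signal.

    ``sigma`` is expressed as a fraction of the curve's total reporter
    concentration (default 1 %, typical stopped-flow fluorescence
    precision).
    """

    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")


@dataclass(frozen=True)
class ExperimentSuite:
    """A labelled set of assay designs sharing generator truth and noise."""

    label: str
    designs: tuple[AssayDesign, ...]
    truth: KineticParameters
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        forms = {d.ras_form for d in self.designs if d.ras_total > 0}
        if len(forms) > 1:
            raise ValueError("designs in a suite must share the RAS form")
        cof = {(d.cofactor_id, d.cofactor_conc) for d in self.designs}
        if len(cof) > 1:
            raise ValueError("designs in a suite must share the cofactor context")


def default_time_grid(truth: KineticParameters,
                      protease_total: float = PROTEASE_TOTAL_M,
                      n_points: int = 201) -> np.ndarray:
    """Observation grid scaled so an uninhibited curve is ~90 % complete.

    The uninhibited reporter curve is ``S0 * (1 - exp(-k_rep * P * t))``;
    the grid ends at ``ln(10) / (k_rep * P)``, comfortably past the 50 %
    consumption the titration design calls for.
    """
    t_end = np.log(10.0) / (truth.k_rep * protease_total)
    return np.linspace(0.0, t_end, n_points)


def build_ras_titration_suite(ras_form: str, truth: KineticParameters,
                              cofactor_id: str = "none",
                              cofactor_conc: float = 0.0,
                              label: str | None = None,
                              noise: NoiseModel | None = None
                              ) -> ExperimentSuite:
    """RAS titration: 6 curves, RAS 0–20 µM at fixed protease and reporter."""
    grid = default_time_grid(truth)
    designs = tuple(
        AssayDesign(protease_total=PROTEASE_TOTAL_M, ras_total=ras,
                    reporter_total=REPORTER_TOTAL_M, time_grid=grid,
                    ras_form=ras_form, r1_initial=0.0,
                    cofactor_id=cofactor_id, cofactor_conc=cofactor_conc)
        for ras in RAS_TITRATION_M
    )
    return ExperimentSuite(label=label or f"ras_titration_{ras_form}",
                           designs=designs, truth=truth,
                           noise=noise or NoiseModel())


def build_kp_titration_suite(truth: KineticParameters,
                             cofactor_id: str = "none",
                             cofactor_conc: float = 0.0,
                             label: str = "r1_inhibition",
                             noise: NoiseModel | None = None
                             ) -> ExperimentSuite:
    """r1 inhibition: 6-point log grid (50 nM–3.3 µM) × 3 reporter levels."""
    r1_grid = np.geomspace(R1_MIN_M, R1_MAX_M, 6)
    grid = default_time_grid(truth)
    designs = tuple(
        AssayDesign(protease_total=PROTEASE_TOTAL_M, ras_total=0.0,
                    reporter_total=s0, time_grid=grid, r1_initial=r1,
                    cofactor_id=cofactor_id, cofactor_conc=cofactor_conc)
        for s0 in KP_REPORTER_M for r1 in r1_grid
    )
    return ExperimentSuite(label=label, designs=designs, truth=truth,
                           noise=noise or NoiseModel())


def add_noise(curve: ProgressCurve, model: NoiseModel) -> ProgressCurve:
    """Overlay seeded additive Gaussian noise on a noiseless curve."""
    if curve.noise_sigma > 0:
        raise ValueError("curve already carries noise")
    rng = np.random.default_rng(model.seed)
    scale = model.sigma * curve.design.reporter_total
    noisy = curve.amc + rng.normal(0.0, scale, size=curve.amc.size) \
        if scale > 0 else curve.amc.copy()
    return ProgressCurve(time=curve.time.copy(), amc=noisy,
                         design=curve.design, noise_sigma=scale,
                         seed=model.seed)


def simulate_suite(suite: ExperimentSuite, noisy: bool = True,
                   mode: str = "rapid_equilibrium") -> list[ProgressCurve]:
    """Simulate every design in a suite, optionally overlaying noise.

    Per-curve noise seeds are spawned deterministically from the suite's
    noise seed, so regeneration is bit-identical.
    """
    seeds = np.random.SeedSequence(suite.noise.seed).generate_state(
        len(suite.designs))
    curves = []
    for design, seed in zip(suite.designs, seeds):
        curve, _ = simulate_progress(design, suite.truth, mode=mode)
        if noisy and suite.noise.sigma > 0:
            curve = add_noise(curve, NoiseModel(sigma=suite.noise.sigma,
                                                seed=int(seed)))
        curves.append(curve)
    return curves


def substrate_conc_from_absorbance(A324: float, pathlength: float = 1.0
                                   ) -> float:
    """Reporter concentration (M) from A324, using ε = 16 mM⁻¹cm⁻¹."""
    if not np.isfinite(A324) or A324 < 0:
        raise ValueError("absorbance must be finite and >= 0")
    if not np.isfinite(pathlength) or pathlength <= 0:
        raise ValueError("pathlength must be > 0")
    epsilon_per_M_cm = 16.0 * 1000.0
    return A324 / (epsilon_per_M_cm * pathlength)
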