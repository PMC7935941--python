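#!/usr/bin/env python
"""Generate the synthetic assay suites for all four protease·RAS pairs.

Writes, per combination, a curve table (1 %-noise progress curves of AMC
release: 100 nM protease, 1 µM reporter, RAS titrated 0–20 µM) plus the
r1-fragment inhibition titration used to pin K_P, under results/suites/.
"""

from pathlib import Path

from raskinetics.io import curves_to_table, write_curves
from raskinetics.synthetic import (COFACTOR_FOR_VARIANT, REFERENCE_TRUTH,
                                   NoiseModel, build_kp_titration_suite,
                                   build_ras_titration_suite, simulate_suite)

OUT = Path(__file__).resolve().parent.parent / "results" / "suites"
OUT.mkdir(parents=True, exist_ok=True)

for (variant, form), truth in sorted(REFERENCE_TRUTH.items()):
    cof_id, cof_conc = COFACTOR_FOR_VARIANT[variant]
    suite = build_ras_titration_suite(form, truth, cofactor_id=cof_id,
                                      cofactor_conc=cof_conc,
                                      noise=NoiseModel(sigma=0.01, seed=0))
    curves = simulate_suite(suite)
    ids = [f"{variant}_{form}_ras{d.ras_total * 1e6:g}uM"
           for d in suite.designs]
    path = OUT / f"ras_titration_{variant}_{form}.csv"
    write_curves(curves_to_table(curves, ids=ids), path)
    print(f"{path.name}: {len(curves)} curves, truth k2/KS = "
          f"{truth.specificity:,.0f} /M/s")

for variant in ("I", "N"):
    truth = REFERENCE_TRUTH[(variant, "active")]
    cof_id, cof_conc = COFACTOR_FOR_VARIANT[variant]
    suite = build_kp_titration_suite(truth, cofactor_id=cof_id,
                                     cofactor_conc=cof_conc,
                                     noise=NoiseModel(sigma=0.01, seed=1000))
    curves = simulate_suite(suite)
    ids = [f"{variant}_r1_{d.r1_initial * 1e9:.0f}nM_S{d.reporter_total * 1e6:g}uM"
           for d in suite.designs]
    path = OUT / f"r1_inhibition_{variant}.csv"
    write_curves(curves_to_table(curves, ids=ids), path)
    print(f"{path.name}: {len(curves)} curves (K_P titration)")
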