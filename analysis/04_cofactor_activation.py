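#!/usr/bin/env python
"""Cofactor activation curves and cognate/non-cognate discrimination.

The published activation data are graphical only, so this driver builds
illustrative datasets with the qualitative features of the measured
curves — saturating activation of the engineered proteases by their
cognate cofactor, and a ~100-fold cognate/near-cognate gap at 1 mM
cofactor — fits the saturation model, and evaluates the two-state
conformational-selection picture. Writes results/cofactor.json.
"""

import json
from pathlib import Path

import numpy as np

from raskinetics.cofactor import (ActivationParameters, activation_value,
                                  cognate_fold, fit_activation,
                                  two_state_linkage)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

# illustrative truth: cognate substrate couples to cofactor binding,
# the near-cognate one barely activates (weak binding, no rescue)
cognate = ActivationParameters(v0=50.0, v_max=2.5e4, K_act=3e-4, h=1.0)
noncog = ActivationParameters(v0=10.0, v_max=250.0, K_act=3e-3, h=1.0)

rng = np.random.default_rng(0)
conc = np.geomspace(1e-5, 1e-2, 8)
v = activation_value(conc, cognate) * (1 + 0.05 * rng.standard_normal(8))
fit = fit_activation(np.column_stack([conc, v]), h=1.0)

fold_1mM = cognate_fold(cognate, noncog, 1e-3)
print(f"fitted activation: v_max = {fit.params.v_max:,.0f} /M/s, "
      f"K_act = {fit.params.K_act * 1e3:.2f} mM "
      f"(truth {cognate.K_act * 1e3:.2f} mM)")
print(f"cognate / near-cognate specificity at 1 mM cofactor: "
      f"{fold_1mM:,.0f}-fold")

# two-state linkage: how cognate sub-site energy shifts the
# active-conformation population at fixed cofactor
linkage = {f"delta_g={d:g}": two_state_linkage(50.0, 3e-4, d, 1e-3)
           for d in (1.0, 5.0, 25.0, 125.0)}
for k, f in linkage.items():
    print(f"  activatable fraction at 1 mM cofactor, {k}: {f:.3f}")

doc = {"fit": {"v0": fit.params.v0, "v_max": fit.params.v_max,
               "K_act_M": fit.params.K_act, "stderr": fit.stderr},
       "cognate_fold_at_1mM": fold_1mM,
       "two_state_linkage_at_1mM": linkage}
(OUT / "cofactor.json").write_text(json.dumps(doc, indent=2,
                                              default=float) + "\n")
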