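"""Forward predictions of the two-step pinch model.

Shows the enhancement factor exp(c*min(E,cap)/RT), the harmonic
composition with the chemical step, and the acceleration bound from
lowering the barrier by the full 4 kcal/mol plateau.
"""

import math

import numpy as np

from ribopinch import PinchParams, conf_rate, effective_kobs, enhancement_factor

p = PinchParams()  # c=0.38, E_cap=4, k_chem=1 /s, 37 C
print(f"baseline (unstructured P1.2): k_conf = {conf_rate(p, 0.0):.2e} /s")
for E in [0.0, 2.0, 4.0, 6.0]:
    print(f"  E_P1.2 = {E:3.0f} kcal/mol: enhancement = "
          f"{enhancement_factor(p, E):6.2f}x, k_obs = "
          f"{effective_kobs(p, E):.3e} /s")

full = PinchParams(c=1.0, E_cap=4.0)
enh = enhancement_factor(full, 4.0)
print(f"full 4 kcal/mol barrier lowering: {enh:.0f}x "
      f"(log10 = {math.log10(enh):.2f}) — just under three orders of magnitude")
print("Past the cap k_obs flattens at the chemistry-limited rate: extra "
      "helix stability no longer buys speed.")
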