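"""Estimate the Mg2+ Hill coefficient in the sub-saturation regime.

The titration stays far below K_half (0.1-3 mM against K_half = 100 mM),
so k_max is not identifiable — exactly the situation the reparameterized
nonlinear fit is built for.  The log-log slope slightly underestimates n
because of residual curvature; the two estimates agreeing within ~0.05
is the expected concordance.
"""

import numpy as np

from ribopinch import fit_hill_nonlinear, fit_loglog_slope, gen_titration

tit = gen_titration(n_true=1.06, K_half=100.0, k_max=10.0,
                    mg_grid=np.geomspace(0.1, 3.0, 8))

ll = fit_loglog_slope(tit, check_saturation=False)
nl = fit_hill_nonlinear(tit)

print(f"log-log slope:     n = {ll.n:.3f}")
print(f"nonlinear Hill fit: n = {nl.n:.3f} (saturation observed: {nl.saturation_flag})")
print("n ~ 1 means a single kinetically relevant Mg2+ ion; the small "
      "log-log/nonlinear gap reflects sub-saturation curvature.")
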