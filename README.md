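# ribopinch

Quantitative analysis of how a peripheral helical domain activates
HDV-like self-cleaving ribozymes.

Large HDV-like ribozymes (such as the *Anopheles gambiae* Agam-2-1
sequence) carry a helix — P1.2 — inside the J1/2 joining region, far
from the catalytic core. Stabilizing that peripheral helix "pinches"
the P1 and P2 helices into proximity and accelerates self-scission by
orders of magnitude. `ribopinch` implements the complete quantitative
workflow behind that observation:

- **kinetics** — mono- and biexponential fitting of fraction-intact
  time courses with multi-start least squares and AICc model selection;
  k_obs is the faster fitted rate.
- **mg_hill** — Hill-coefficient estimation from Mg²⁺ titrations by the
  log-log slope and by a nonlinear fit reparameterized for the
  sub-saturation regime (where k_max is not identifiable).
- **energetics** — apparent activation energies
  E_a = −RT·ln(k_obs/k_uncat) against a configurable uncatalyzed
  baseline, with explicit constants (R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹).
- **helix_thermo** — nearest-neighbor ΔG°₃₇ of the P1.2 helix
  (bundled Turner-2004-style table, G·U allowed) and information
  content at 2 bits per base pair.
- **coupling** — OLS of E_a against helix stability (the coupling
  fraction: slope dE_a/dΔG ≈ 0.38), a linear-then-flat hinge fit that
  localizes the ~4 kcal/mol (~17 kJ/mol) usable-stability plateau, and
  the log-linear information–activity fit (fold change per 10 bits).
- **pinch_model** — the forward two-step model
  k_conf = A·exp(−(E_a0 − c·min(E_P1.2, E_cap))/RT),
  1/k_obs = 1/k_conf + 1/k_chem, used for prediction and as the
  generative core of synthetic panels.
- **synthetic** — generators for noisy time courses, sub-saturation
  titrations and construct ladders, so the whole pipeline is testable
  with no experimental input.

## Worked example

Simulate a construct panel under the pinch model, convert rates to
apparent activation energies, and recover the coupling fraction and
plateau (this is `examples/04_energy_coupling.py`):

```python
import numpy as np
from ribopinch import (PinchParams, apparent_Ea, hinge_fit,
                       linear_coupling_fit, simulate_panel)

p = PinchParams(c=0.38, E_cap=4.0, k_chem=1e9)
panel = simulate_panel(p, np.linspace(0.0, 7.0, 15))
for rec in panel:
    rec.E_a_apparent = apparent_Ea(rec.k_obs, 2e-10, rec.condition)

lin = linear_coupling_fit([r for r in panel if -r.stability <= 3.5])
hinge = hinge_fit(panel)
```

Output:

```
linear fit (below cap): slope dEa/ddG = 0.380, r^2 = 1.0000
hinge fit (full range): slope = 0.380, breakpoint = 4.00 kcal/mol
```

The slope says that 38% of the P1.2 folding free energy is spent
lowering the activation barrier of the rate-limiting conformational
change; the breakpoint marks where the chemical step (k_chem ≈ 1 s⁻¹)
takes over as rate-limiting and extra helix stability stops helping.
The other scripts in `examples/` walk through each capability the same
way (kinetic fitting, Hill analysis, helix scoring, forward
predictions, the config-driven pipeline).

A thin CLI mirrors the library for shell use:

```
ribopinch synth titration --seed 1 --out tit.csv
ribopinch fit-hill tit.csv --out hill.json
ribopinch run-all --config config.yaml
```

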