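# Methods

## The system and the model

HDV-like self-cleaving ribozymes fold into a nested double pseudoknot
whose catalytic core cleaves the RNA at the 5′ end of the P1 helix.
In the large variants studied here, the J1/2 joining region between P1
and P2 contains a peripheral helix, P1.2. The package models activation
by this peripheral domain as a two-step scheme:

1. a rate-limiting conformational change that juxtaposes P1 and P2
   ("the pinch"), with rate
   `k_conf = A · exp(−(E_a0 − c·min(E_P1.2, E_cap))/RT)`, where
   E_P1.2 ≥ 0 is the magnitude of the P1.2 formation free energy, c is
   the coupling fraction, and E_cap is the maximum usable stability;
2. the chemical (transphosphorylation) step at rate k_chem.

The observed rate composes the steps harmonically,
`1/k_obs = 1/k_conf + 1/k_chem`, which reproduces both limits smoothly:
conformational-change-limited kinetics for weak P1.2 helices and the
chemistry-limited plateau (k_obs → k_chem) for strong ones. A hard
`min(k_conf, k_chem)` alternative is available via
`PinchParams(combination="min")`. The cap is implemented inside
`conf_rate` as hard saturation of the barrier lowering; an equivalent
phenomenology (saturation purely from the k_chem plateau) can be
obtained by setting `E_cap` large and k_chem small — both give a
rise-then-flat E_a-vs-stability curve.

Catalytic proficiency is placed on an energy scale as the apparent
activation energy `E_a = −RT·ln(k_obs/k_uncat)` relative to the
background cleavage rate of an unconstrained phosphodiester under
matched conditions. This is a bookkeeping definition, not a claim that
k_obs is a single elementary step.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| c (coupling fraction) | – | 0.38 | fraction of P1.2 folding energy spent lowering the conformational barrier; the central fitted quantity |
| E_cap | kcal/mol | 4.0 | usable-stability plateau (~17 kJ/mol); beyond it the conformational step is no longer rate-limiting |
| k_chem | s⁻¹ | 1.0 | chemistry-limited rate scale of optimally folding constructs |
| A | s⁻¹ | 1×10¹⁰ | Arrhenius pre-exponential; with E_a0 sets the zero-stability baseline |
| E_a0 | kcal/mol | 19.87 | chosen so an unstructured-P1.2 construct cleaves on the hours scale (k_conf(0) ≈ 1×10⁻⁴ s⁻¹); a package choice, declared here, not a measured constant |
| T | K | 310.15 | assay temperature (37 °C); RT = 0.61633 kcal/mol |
| R | kcal·mol⁻¹·K⁻¹ | 1.98720×10⁻³ | carried in kcal units to match the field's presentation |
| k_uncat (constant mode) | s⁻¹ | 2×10⁻¹⁰ | order-of-magnitude background cleavage rate at 37 °C/pH 7.5; see below |

Only the *differences* of E_a across constructs at a fixed condition
enter the coupling regressions, so the absolute baseline k_uncat
cancels there — this is why a constant-mode baseline is the default and
is safe. The parameterized mode (bundled
`data/uncat_baseline.yaml`) adds first-order hydroxide dependence
(one decade per pH unit in the base-catalyzed regime), Arrhenius
temperature scaling (Ea ≈ 29.9 kcal/mol) and a linear Mg²⁺ acceleration
factor; its coefficients are order-of-magnitude transcriptions of the
established background-cleavage behavior and only matter for
cross-condition comparisons.

## Fitting procedures and numerical choices

**Exponential fits.** `scipy.optimize.least_squares` (trust-region
reflective) with bounds: rates in [10⁻⁷, 10³] s⁻¹, amplitudes and
plateau in [0, 1]. Biexponential surfaces are multimodal, so fits run
from all ordered pairs of ≥ 5 log-spaced rate seeds spanning the
observed time window and keep the lowest-cost converged solution.
Rates are reported sorted descending and `k_obs = rates[0]` by
definition. The plateau (persistent uncleaved fraction) is free by
default and can be pinned (`fix_plateau=0`); whether the two amplitudes
are additionally tied to `1 − plateau − A1` is configurable
(`amplitudes_sum_to_one`), since either convention is defensible for
gel-quantified data. Model selection uses corrected AIC
(`n·ln(rss/n) + 2p + 2p(p+1)/(n−p−1)`), appropriate at the 8–12 time
points of a typical assay; when the extra parameters buy no real rss
improvement (including both fits at machine precision on noiseless
data) the simpler model wins outright, and an extra-sum-of-squares
F-test is available as an alternative criterion. Degenerate inputs
(constant fraction intact) raise rather than fit.

**Hill fits.** The log-log estimator is the OLS slope of
log k_obs vs log [Mg²⁺], valid when the titration stays far below
K_half; it warns when a quick nonlinear fit places K_half within a
decade of the highest concentration. The nonlinear estimator fits
log k = log c + n·log m − log(1 + (m/K)ⁿ) with parameters
(log₁₀ c, n, log₁₀ K): c = k_max/Kⁿ is the lumped sub-saturation scale,
so n stays identifiable when saturation was never observed and K only
enters through the curvature term. Multi-start over log K. The
`saturation_flag` (max tested concentration ≥ fitted K_half) marks
whether k_max and K_half individually mean anything.

**Coupling regressions.** Internally all fits run on the stability
*magnitude* x = −ΔG°₃₇ ≥ 0; the reported `slope` is dE_a/dΔG (positive,
the literature convention) and `slope_vs_magnitude` is its negation.
The wild-type record is excluded by default (toggleable), since the
linear relationship is a statement about the designed variant series.
The hinge model `E_a = b₀ + b₁·min(x, x₀)` is profiled over a 0.1
kcal/mol breakpoint grid across the observed range (closed-form OLS at
each candidate) and kept only when it beats the plain line on AICc
(3 vs 2 parameters); flat or purely linear data therefore fall back to
the linear fit — slope 0 and no breakpoint for flat input. Grouped
fits (`group_by_linker=True`) require a uniform condition per group and
raise otherwise; the pooled fit permits mixed conditions with a
warning, because per-condition and pooled analyses are both legitimate
and the choice is left to the caller.

**Helix thermodynamics.** Additive nearest-neighbor model: duplex
initiation (+4.10 kcal/mol) + one stacking term per adjacent-pair step
+ a +0.50 kcal/mol penalty per terminal A-U or G-U pair + an optional
hairpin-loop penalty (tabulated for 3–9 nt, Jacobson–Stockmayer
extrapolation beyond). The bundled table carries Turner-2004-style
ΔG°₃₇ values for all 36 WC/G·U steps and is validated for completeness
and strand-flip symmetry on load; any table in the same CSV layout can
be swapped in. Internal loops and bulges are rejected rather than
approximated — the P1.2 variant series consists of contiguous helices.
Full pseudoknot minimum-free-energy prediction is out of scope: a
pseudoknot-aware folding program run by the user can supply per-
construct MFE values through the `stability` field of
`ConstructRecord`, and the nearest-neighbor domain energy is the
built-in covariate. Absolute MFEs from such programs are not
reproducible by any additive helix model; only relative stability
trends are meaningful here, and the regressions are invariant to a
constant offset in stability.

## What the synthetic generators emulate — and what they don't

`gen_timecourse` produces multi-exponential fraction-intact decays with
additive Gaussian noise (densitometry-like), clipped to [0, 1] with
clipping logged; clipping bias is negligible at sd ≤ 0.05, which is why
clipping was preferred over truncated sampling. `gen_titration`
produces Hill-model rates with multiplicative log-normal noise
(between-replicate-like). `gen_construct_ladder` converts a base-pair
count into stability at a mean stack magnitude of 0.81 kcal/mol/bp
(a typical mixed-sequence RNA stack; with c = 0.38 this reproduces the
~12-fold rate increase per 10 bits, since exp(0.38·5·0.81/RT) ≈ 12.15)
and into rates through the pinch model.
`gen_timecourse_replicates` produces independent noisy replicates of
one decay (default 2, the usual minimum behind a reported rate
constant), with per-replicate seeds spawned from the master seed.
Every generator is a pure function of (parameters, seed); noise
without a seed raises.

The emulated Mg²⁺ design uses 0.1–3 mM against K_half = 100 mM — a
stated modelling assumption for the sub-saturation regime, not a
measured binding constant. Real data differ from these emulations in
ways the tests cannot probe: gel quantification errors are correlated
within a lane, misfolded subpopulations need not be exactly
biexponential, replicate noise is not exactly log-normal, and real
P1.2 variants change sequence context as well as stability. Passing
recovery tests therefore demonstrate that the estimators are correct
and unbiased under the assumed noise models at realistic sizes — not
that those noise models capture every feature of phosphorimager data.

## Problem sizes

Recovery suites use 200 twelve-point time courses (noise sd 0.02),
8-point titrations, 10–15-construct panels, and 40–60 replicate panels
for the Monte-Carlo centering checks — the same order as the
experimental designs they emulate. At noise sd 0.3 kcal/mol on E_a a
single 12-construct panel determines the coupling slope only to
±0.08 (1 se), so the seeded invariant checks that the estimator
*centers* on the generating value; tighter single-panel statements are
made at sd 0.15.

## Known limitations

- The uncatalyzed baseline's parameterized coefficients are
  order-of-magnitude transcriptions; cross-condition E_a comparisons
  inherit that uncertainty (within-condition differences do not).
- The hinge breakpoint is profiled on a grid, so its resolution is the
  grid step (0.1 kcal/mol) and no confidence interval is reported.
- No mechanistic two-metal-ion binding model; cooperative Hill
  coefficients (1.7–2) typical of related ribozymes are discussed only
  as context.
- The hypothesized partially stable folding intermediate is not
  modelled — the two-state scheme holds the precursor/activated/product
  energies fixed by construction, and the chemistry is treated as
  irreversible (the cleaved leader dissociates).
- The ~3-orders-of-magnitude acceleration can be totalled either as
  exp(ΔE/RT) at full barrier lowering (exposed as
  `enhancement_factor` with c = 1: log₁₀ = 2.82) or as the coupled
  product across the stability range; the package exposes both and
  uses the former as the headline bound.
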