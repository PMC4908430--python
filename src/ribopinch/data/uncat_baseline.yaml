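# Baseline (uncatalyzed) RNA phosphodiester cleavage-rate model.
#
# k_ref_per_s is the background transesterification rate at the reference
# condition (37 C, pH 7.5, 150 mM monovalent, 1 mM Mg2+), of order the
# canonical ~1e-10..1e-9 s^-1 scale for an unconstrained phosphodiester
# under near-physiological solution conditions.  The coefficient table is
# an order-of-magnitude transcription of the established empirical
# behavior of this background reaction: first-order hydroxide dependence
# above the pH-independent regime, Arrhenius temperature scaling with
# Ea ~ 30 kcal/mol, and roughly linear divalent-ion acceleration.
#
# Downstream activation-energy regressions use differences of E_a across
# constructs at a FIXED condition, so the absolute value of this baseline
# cancels there; only cross-condition comparisons depend on it.
mode: constant
k_ref_per_s: 2.0e-10
ref_condition:
  temperature: 310.15
  pH: 7.5
  monovalent_mM: 150.0
  mg_mM: 1.0
coefficients:
  pH_slope: 1.0            # decades of rate per pH unit (base-catalyzed regime)
  Ea_uncat_kcal: 29.9      # Arrhenius activation energy, kcal/mol
  mg_linear_per_mM: 2.5    # rate factor 1 + coeff * [Mg2+]/mM
  monovalent_exponent: 0.0
provenance: >-
  Empirical background-cleavage rate law for unconstrained RNA
  phosphodiesters (transcribed order-of-magnitude coefficients);
  swap this file to use a different baseline.
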