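# Metabolic regression coefficients, one entry per metabolic group.
#
# Ectotherm groups use an Arrhenius mass-temperature regression
#   ln I = ln_x0 + a * ln M - E / (k T)
# with I the per-individual metabolic rate in J h^-1, M the fresh body mass
# in mg, T the absolute temperature in K and k the Boltzmann constant
# (8.617333e-5 eV K^-1).  Endotherm groups use a temperature-independent
# power law  I = exp(ln_x0) * M^a  (same units).
#
# The shipped values follow the form and magnitude of published invertebrate
# group regressions and a bird basal-metabolism allometry; substitute the
# coefficients of your own sources here for exact benchmark work.
groups:
  invertebrate:            # general terrestrial invertebrate regression
    kind: ectotherm_arrhenius
    ln_x0: 23.055
    a: 0.695
    E: 0.686
  insect:
    kind: ectotherm_arrhenius
    ln_x0: 21.972
    a: 0.759
    E: 0.657
  arachnid:
    kind: ectotherm_arrhenius
    ln_x0: 24.581
    a: 0.565
    E: 0.762
  earthworm:
    kind: ectotherm_arrhenius
    ln_x0: 23.055
    a: 0.695
    E: 0.686
  bird:
    kind: endotherm_power
    ln_x0: -1.677           # I = 0.187 * M_mg^0.69 J h^-1 (basal metabolism)
    a: 0.69
    E: 0.0
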