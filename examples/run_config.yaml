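# Example run configuration for the `ecoflux` CLI (ecoflux all --config ...).
# Exactly one of `generator` / `input_paths` selects the input.
seed: 1
output_dir: ecoflux_out

generator:
  n_plots_per_system: 8
  biomass_sigma: 0.6

# input_paths:
#   guilds: data/guilds.csv
#   plots: data/plots.csv
#   trees: data/trees.csv

params:
  omnivory: 0.2
  self_predation: 0.0
  size_structure: 0.0
  spatial_structure: 0.0
  protection_use: 0.0
  ppmr_log10_optimum: 2.0
  min_diet_fraction: 0.01

# optional robustness stages
sweep_parameters: []          # e.g. [omnivory, protection_use]
h_max_list: []                # e.g. [14, 16, 18, 20, 22]
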