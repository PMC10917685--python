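# Assimilation efficiencies (fraction of ingested energy that is
# metabolizable by the consumer).
#
# Basal resources use the lookup table below.  Animal prey use, by default,
# a log-linear function of the prey's nitrogen content,
#   e = clip(slope * ln(%N) + intercept, 0.01, 1),
# whose coefficients are calibrated so that low-N detritivore prey
# (~6% N, e.g. millipedes) come out near 0.61 and high-N predator prey
# (~11% N, e.g. centipedes, earthworms) near 0.97.
mode: nitrogen_equation
lookup:
  plants: 0.21
  litter: 0.18
  som: 0.13
  bacteria: 0.96
  fungi: 0.36
  animal: 0.90            # fallback for lookup mode when no guild entry exists
equation:
  slope: 0.594
  intercept: -0.454
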