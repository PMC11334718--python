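# Small demonstration pipeline: build the channel, generate a synthetic
# trajectory, analyse permeation and structure, compute the axial potential
# and reconstruct the two packaged reference PMFs.
stages: [build, simulate, analyze-permeation, analyze-structure, potential, wham]
seed: 0
build:
  chiral_n: 7
  chiral_m: 7
  strain: 0.10
  section_length: 13.34
generator:
  n_events: 60
  na_fraction: 0.05
geometry:
  entrance_z: -6.67
  exit_z: 6.67
  buffer: 2.0
umbrella:
  samples_per_window: 1500
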