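# Zero-edit demo: a small phantom cohort through selection, classification
# and group statistics (LiFE off to keep the run light; enable stages.life
# to filter candidates against simulated diffusion signal first).
seed: 42
n_subjects: 4
phantom:
  n_streamlines: 20
candidates:
  n_true: 100
  n_spurious: 40
stages:
  life: false
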