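# lac-reporter circuit with both competition channels enabled.
# Omitted parameters fall back to the package defaults
# (dualosc.params.DEFAULT_PARAMETERS); unknown keys are rejected.
circuit:
  reporter_kind: lac
  retroactivity_on: true
  protease_sharing_on: true
  n_activator_dna: 50
  n_repressor_dna: 25
parameters:
  b_d2: 7.48          # lac reporter maximum transcription rate (mRNA/copy/min)
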