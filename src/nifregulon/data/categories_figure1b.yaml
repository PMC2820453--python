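# Default 5-label functional-category vocabulary for core-subset summaries.
# Labels mirror the major groups seen in nitrogen-fixation regulons:
# nitrogenase synthesis/maturation/function, regulation and signal
# transduction, transport and metabolism, energy production/conversion,
# and proteins of unknown function.
categories:
  - nif
  - regulation_signalling
  - transport_metabolism
  - energy
  - unknown
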