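# Author-abbreviation equivalence table, applied segment-wise after
# diacritic stripping and case folding.  Keys normalise to values.
# version: 1
equivalences:
  fil: f
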