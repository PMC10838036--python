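# Taxonomic-status vocabulary normalisation, applied case-insensitively
# to the status column of GBIF exports.  Unknown strings map to
# "doubtful" with a warning.
# version: 1
statuses:
  accepted: accepted
  synonym: synonym
  "homotypic synonym": synonym
  "heterotypic synonym": synonym
  "proparte synonym": synonym
  doubtful: doubtful
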