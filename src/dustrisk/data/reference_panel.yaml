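# Reference panel for enrichment and ecological screening.
# background: Texas-specific soil background concentrations, mg/kg.
#   Cd has a published background of 0 -> EF-ineligible (enrichment factor
#   undefined); requests for Cd EF raise a configuration error.
# esv: Region 4 soil ecological screening values, mg/kg (absent where no
#   screening value is published).
reference_element: Al
background:
  Al: 30000
  As: 5.9
  Cd: 0
  Cr: 30
  Cu: 15
  Fe: 15000
  Ni: 10
  Pb: 30
  Zn: 15
  Mn: 300
esv:
  As: 18
  Cd: 0.36
  Cr: 23
  Cu: 28
  Ni: 38
  Pb: 11
  Zn: 46
  Mn: 220
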