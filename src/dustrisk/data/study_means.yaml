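# Published study-wide arithmetic mean concentrations for the 31-residence
# Southeast Texas household dust survey (mg/kg dry dust; TB/EB in cfu/g).
# These summary values are inputs to desk-scale recomputations (study-mean
# enrichment factors, study-mean health risk) and calibrate the synthetic
# survey generator.
mean:
  Al: 3738
  As: 3.6
  Cd: 1.9
  Cr: 23
  Cu: 53
  Fe: 2939
  Ni: 12
  Pb: 38
  Zn: 368
  Na: 17387
  Mg: 2900
  K: 2872
  Ca: 8030
  Mn: 48.2
  TB: 47714
  EB: 11833
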