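# Per-element toxicity reference table for the seven priority heavy metals.
#
# rfd_*: route-specific chronic reference doses, mg/kg/day (IRIS-style
#        values as commonly used in dust/soil health-risk screening;
#        dermal RfD = oral RfD x gastrointestinal absorption fraction).
# sf_*:  cancer slope factors, (mg/kg/day)^-1; omitted (null) where no
#        published oral/dermal slope factor exists (Cu, Pb, Zn) -- such
#        elements appear in hazard-quotient output only.
# abs:   dermal absorption fraction from dust, dimensionless.  A single
#        default of 0.01 is used for every element: the published
#        ingestion:dermal risk ratios are constant across elements, which
#        is only consistent with one shared ABS value.
#
# These values are editable screening defaults, not study measurements.
elements:
  As:
    rfd_ingestion: 3.0e-4
    rfd_dermal: 1.23e-4
    rfd_inhalation: 3.01e-4
    sf_ingestion: 1.5
    sf_dermal: 1.5
    sf_inhalation: 15.1
    abs: 0.01
  Cd:
    rfd_ingestion: 1.0e-3
    rfd_dermal: 1.0e-5
    rfd_inhalation: 1.0e-3
    sf_ingestion: 6.1
    sf_dermal: 6.1
    sf_inhalation: 6.3
    abs: 0.01
  Cr:
    rfd_ingestion: 3.0e-3
    rfd_dermal: 6.0e-5
    rfd_inhalation: 2.86e-5
    sf_ingestion: 0.5
    sf_dermal: 0.5
    sf_inhalation: 42.0
    abs: 0.01
  Cu:
    rfd_ingestion: 4.0e-2
    rfd_dermal: 1.2e-2
    rfd_inhalation: 4.02e-2
    abs: 0.01
  Ni:
    rfd_ingestion: 2.0e-2
    rfd_dermal: 5.4e-3
    rfd_inhalation: 2.06e-2
    sf_ingestion: 1.7
    sf_dermal: 1.7
    sf_inhalation: 0.84
    abs: 0.01
  Pb:
    rfd_ingestion: 3.5e-3
    rfd_dermal: 5.25e-4
    rfd_inhalation: 3.52e-3
    abs: 0.01
  Zn:
    rfd_ingestion: 3.0e-1
    rfd_dermal: 6.0e-2
    rfd_inhalation: 3.0e-1
    abs: 0.01
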