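# Cohort exposure parameters for the dust ingestion / dermal / inhalation
# average-daily-dose model.
#
# Cohorts: young_child (<6 y), older_child (6-18 y), adult (>18 y).
# Units: igr mg/day; ef_days days/year; ed years; bw kg; sa cm^2;
#        af mg/cm^2/day; ihr m^3/day; pef m^3/kg; cf kg/mg.
#
# Ingestion rates are standard USEPA dust-HRA defaults (200 mg/day for
# children, 100 mg/day for adults); they are not study-measured values.
# Averaging time: AT = 365 x ED days for non-carcinogenic risk; for
# carcinogenic risk either 365 x lifetime_years ("as_stated", default) or
# 365 x ED ("as_tabulated") -- see docs/methods.md for why both exist.
cf: 1.0e-6
ef_days: 365
ihr: 20
pef: 1.36e9
lifetime_years: 70
cohorts:
  young_child:
    igr: 200
    ed: 6
    bw: 15
    sa: 2336
    af: 0.2
  older_child:
    igr: 200
    ed: 12
    bw: 48
    sa: 4591
    af: 0.2
  adult:
    igr: 100
    ed: 30
    bw: 70
    sa: 6034
    af: 0.07
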