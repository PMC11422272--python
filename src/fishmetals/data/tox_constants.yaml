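# Toxicological constants and exposure-model parameters.
# Units are stated per key; all values are overridable at load time.

exposure:
  EF_days_per_year: 365        # exposure frequency
  ED_years: 70                 # exposure duration
  AT_days: 25500               # averaging time (used verbatim; note 365*70 = 25550)

strata:                        # population body weights, kg
  men: 75
  women: 65
  teenagers: 50
  children: 20

scenarios:                     # fish ingestion rates
  FIR1: {daily_g: 5.7, weekly_g: 39.9, annual_kg: 2.08}    # species-specific tilapia intake
  FIR2: {daily_g: 33.1, weekly_g: 231.5, annual_kg: 12.07} # total national fish intake

rfd_mg_per_kg_day:             # oral reference doses; Cu has none (not evaluated)
  Cd: 0.001
  Zn: 0.3
  Pb: 1.0e-05                  # elected protective value (0.01 ug/kg BW/day)
  Cu: null

slope_factor_per_mg_kg_day:    # cancer slope factors; Cu and Zn not classified
  Cd: 1.5
  Pb: 0.0085

pti:                           # provisional tolerable intakes, per kg BW
  Cd: {value: 25.0, unit: ug, period: month}
  Cu: {value: 0.5, unit: mg, period: day}
  Zn: {value: 0.3, unit: mg, period: day}
  Pb: {value: 0.01, unit: ug, period: day}

days_per_month: 30             # month -> day normalisation for the Cd PTI

moisture_fraction:             # tissue water content used for ww <-> dw
  muscle: 0.832
  liver: 0.805
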