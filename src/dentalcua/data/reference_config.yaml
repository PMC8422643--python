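# Base-case configuration: single-molar replacement in a 50-year-old cohort,
# implant-supported single crown (ISC) evaluated against a three-unit fixed
# dental prosthesis (FDP) from the patient perspective, 30-year horizon,
# 3% annual discount rate, costs in CZK, utilities on a 0-100 scale.
#
# The Weibull survival parameters below are CALIBRATED values chosen to give
# the expected qualitative longevity ordering of the three prosthesis types
# (ISC longest-lived, DIB intermediate, FDP shortest at long horizons); they
# are not extracted from any clinical dataset.
schema_version: 1

comparison:
  evaluated: ISC
  comparator: FDP

economics:
  discount_rate: 0.03
  horizon_years: 30
  discount_convention: from_cycle_1
  half_cycle_correction: false
  utility_scale: 100
  cost_band_keying: residence

environment:
  monthly_wage_czk: 36144
  weekly_hours: 40
  weeks_per_month: 4.348
  unemployment_rate: 0.031
  base_fare_czk: 32
  czk_to_usd: 0.048

utilities:       # quality weights, 0-100
  ISC: 74.75
  FDP: 71.47
  DIB: 59.19
  MT: 0.00

costs:
  ISC:
    variants: {A: 35485, B: 36918, C: 48454}
    initial: mean                      # -> 40,286 CZK
    annual_bands: [[1, 2, 3913], [3, 5, 3972], [6, null, 3985]]
  FDP:
    variants: {A: 32352, B: 36514, C: 51616}
    initial: mean                      # -> 40,161 CZK
    annual_bands: [[1, 2, 4048], [3, 5, 4111], [6, null, 4130]]
  DIB:
    initial: 83072.82
    annual_bands: [[1, 2, 4096], [3, 5, 4219], [6, null, 4250]]
  MT:
    entry:
      default: 14358                   # explantation (from ISC, DIB)
      from_FDP: 1600                   # extraction of abutment teeth
    annual_bands: [[1, null, 3864]]

survival:        # calibrated Weibull (shape, scale in years) per prosthesis
  ISC: {family: weibull, shape: 1.6, scale: 48.0, note: calibrated}
  FDP: {family: weibull, shape: 1.8, scale: 28.0, note: calibrated}
  DIB: {family: weibull, shape: 1.7, scale: 35.0, note: calibrated}

arms:
  ISC:
    initial_state: ISC1
    states:
      ISC1: {prosthesis: ISC}
      ISC2: {prosthesis: ISC}
      FDP:  {prosthesis: FDP}
      MT:   {prosthesis: MT, absorbing: true}
    rules:
      ISC1: {ISC2: 1.0}
      ISC2: {FDP: 0.998, MT: 0.002}
      FDP:  {MT: 1.0}
  FDP:
    initial_state: FDP1
    states:
      FDP1: {prosthesis: FDP}
      FDP2: {prosthesis: FDP}
      DIB:  {prosthesis: DIB}
      MT:   {prosthesis: MT, absorbing: true}
    rules:
      FDP1: {FDP2: 1.0}
      FDP2: {DIB: 0.846, MT: 0.154}
      DIB:  {MT: 1.0}
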