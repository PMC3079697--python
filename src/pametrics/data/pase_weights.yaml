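# PASE scoring configuration.
#
# Item weights are EXTERNAL published values (Washburn et al., the original
# PASE scale-development work); they are not derived by this package and are
# shipped here only as editable defaults.  The scorer refuses to run without
# a weights mapping so that the external provenance stays explicit.
#
# Category midpoints convert the ordinal frequency/duration answers to
# days/week and hours/day; work hours map directly to hours/week.
weights:
  walking:           20
  light_sport:       21
  moderate_sport:    23
  strenuous_sport:   23
  muscle_strength:   30
  light_housework:   25
  heavy_housework:   25
  home_repair:       30
  lawn_work:         36
  gardening:         20
  caring_for_others: 35
  work:              21
sedentary_items: [sitting]
frequency_days:
  never: 0.0
  seldom: 1.5      # 1-2 days/week
  sometimes: 3.5   # 3-4 days/week
  often: 6.0       # 5-7 days/week
duration_hours:
  lt1h: 0.5
  h1to2: 1.5
  h2to4: 3.0
  gt4h: 5.0
work_hours_per_week:
  lt1h: 0.5
  h1to4: 2.5
  h5to8: 6.5
  gt8h: 10.0
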