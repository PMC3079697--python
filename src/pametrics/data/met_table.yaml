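# Default MET lookup for AQuAA scoring.
#
# Values are compendium-style energy costs (multiples of resting metabolic
# rate) keyed by activity token and the respondent's perceived intensity
# (low / medium / high).  Perceived intensity selects among plausible MET
# values for the activity; when an activity token is unknown the
# category fallback supplies a generic value for that AQuAA category.
# Edit or replace this file to use a different compendium mapping.
activities:
  television:   {low: 1.0, medium: 1.3, high: 1.5}
  reading:      {low: 1.3, medium: 1.3, high: 1.5}
  office_work:  {low: 1.5, medium: 1.5, high: 1.8}
  walking:      {low: 2.5, medium: 3.0, high: 4.0}
  cycling:      {low: 4.0, medium: 5.0, high: 7.0}
  gardening:    {low: 2.5, medium: 3.5, high: 4.5}
  housework:    {low: 2.0, medium: 3.0, high: 4.0}
  swimming:     {low: 4.5, medium: 6.0, high: 8.0}
  jogging:      {low: 6.0, medium: 7.0, high: 7.5}
  fitness:      {low: 3.5, medium: 5.0, high: 7.0}
category_fallback:
  commuting:    {low: 2.5, medium: 4.0, high: 6.0}
  work_school:  {low: 1.5, medium: 3.0, high: 5.5}
  household:    {low: 2.0, medium: 3.0, high: 4.5}
  leisure:      {low: 1.5, medium: 3.0, high: 5.0}
  sports:       {low: 3.0, medium: 5.0, high: 7.5}
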