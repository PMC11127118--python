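# Default RAI-ICD weight table: the published instrument's integer point
# assignments (score range 0-81).  Age points are tabulated per 5-year band
# jointly with cancer status (age x cancer interaction); functional status
# is tabulated jointly with cognitive decline (the second interaction).
# Grid cells are total points for the cell, not increments.
version: rai-icd-2024
age_cancer:
  "<=19":  {without_cancer: 0,  with_cancer: 43}
  "20-24": {without_cancer: 2,  with_cancer: 43}
  "25-29": {without_cancer: 4,  with_cancer: 43}
  "30-34": {without_cancer: 6,  with_cancer: 44}
  "35-39": {without_cancer: 9,  with_cancer: 44}
  "40-44": {without_cancer: 11, with_cancer: 44}
  "45-49": {without_cancer: 13, with_cancer: 44}
  "50-54": {without_cancer: 15, with_cancer: 44}
  "55-59": {without_cancer: 18, with_cancer: 44}
  "60-64": {without_cancer: 20, with_cancer: 45}
  "65-69": {without_cancer: 22, with_cancer: 45}
  "70-74": {without_cancer: 25, with_cancer: 45}
  "75-79": {without_cancer: 27, with_cancer: 45}
  "80-84": {without_cancer: 29, with_cancer: 45}
  "85-89": {without_cancer: 31, with_cancer: 46}
  "90-94": {without_cancer: 34, with_cancer: 46}
  "95-99": {without_cancer: 36, with_cancer: 46}
  ">=100": {without_cancer: 38, with_cancer: 46}
male_points: 3
deficit_points:
  weight_loss: 2
  poor_appetite: 1
  kidney_failure: 3
  congestive_heart_failure: 3
  shortness_of_breath: 2
function_cognition:
  independent:          {without_cognitive_decline: 0,  with_cognitive_decline: 9}
  partially_dependent:  {without_cognitive_decline: 10, with_cognitive_decline: 15}
  totally_dependent:    {without_cognitive_decline: 20, with_cognitive_decline: 21}
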