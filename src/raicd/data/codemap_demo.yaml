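# Reduced demo code map: one or two representative ICD-10-CM codes per
# RAI-ICD parameter.  For documentation, examples and quick tests only —
# not a clinically usable mapping.
version: demo-v1
parameters:
  weight_loss:
    - R634
  poor_appetite:
    - R630
  congestive_heart_failure:
    - I50
  shortness_of_breath:
    - R0602
  kidney_failure:
    - N186
  cognitive_decline:
    - F0390
  functional_status_partial:
    - Z741
  functional_status_total:
    - Z7401
cancer:
  severe:
    - C34
    - C25
  moderate:
    - C18
  mild:
    - C61
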