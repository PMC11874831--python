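# Charlson weights (1-6, from 1-year mortality hazard ratios) for the
# cancer-adapted condition roster. Hypertension sits outside the Charlson
# index and carries weight 0 by convention here: it contributes to
# comorbidity counts and pattern analysis but not to the CCI score.
weights:
  myocardial_infarction: 1
  congestive_heart_failure: 1
  peripheral_vascular_disease: 1
  cerebrovascular_disease: 1
  dementia: 1
  copd: 1
  connective_tissue_disease: 1
  peptic_ulcer: 1
  mild_liver_disease: 1
  diabetes: 1
  diabetes_with_complications: 2
  paralysis: 2
  renal_disease: 2
  moderate_severe_liver_disease: 3
  aids: 6
  hypertension: 0
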