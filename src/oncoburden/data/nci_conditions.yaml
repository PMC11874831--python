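# ICD-10 prefix lists for the cancer-adapted (NCI) Charlson condition roster,
# following the published Quan et al. ICD-10 coding of Charlson conditions,
# relabeled to the 14-condition cancer-specific roster plus hypertension.
# Prefixes are stored uppercase without dots; matching is prefix-based,
# case- and dot-insensitive.
dialect: quan-icd10-nci15
conditions:
  myocardial_infarction: [I21, I22, I252]
  congestive_heart_failure: [I099, I110, I130, I132, I255, I420, I425, I426,
                             I427, I428, I429, I43, I50, P290]
  peripheral_vascular_disease: [I70, I71, I731, I738, I739, I771, I790, I792,
                                K551, K558, K559, Z958, Z959]
  cerebrovascular_disease: [G45, G46, H340, I60, I61, I62, I63, I64, I65,
                            I66, I67, I68, I69]
  dementia: [F00, F01, F02, F03, F051, G30, G311]
  copd: [I278, I279, J40, J41, J42, J43, J44, J45, J46, J47, J60, J61, J62,
         J63, J64, J65, J66, J67, J684, J701, J703]
  peptic_ulcer: [K25, K26, K27, K28]
  mild_liver_disease: [B18, K700, K701, K702, K703, K709, K713, K714, K715,
                       K717, K73, K74, K760, K762, K763, K764, K768, K769,
                       Z944]
  diabetes: [E100, E101, E106, E108, E109, E110, E111, E116, E118, E119,
             E120, E121, E126, E128, E129, E130, E131, E136, E138, E139,
             E140, E141, E146, E148, E149]
  diabetes_with_complications: [E102, E103, E104, E105, E107, E112, E113,
                                E114, E115, E117, E122, E123, E124, E125,
                                E127, E132, E133, E134, E135, E137, E142,
                                E143, E144, E145, E147]
  paralysis: [G041, G114, G801, G802, G81, G82, G830, G831, G832, G833,
              G834, G839]
  renal_disease: [I120, I131, N032, N033, N034, N035, N036, N037, N052,
                  N053, N054, N055, N056, N057, N18, N19, N250, Z490, Z491,
                  Z492, Z940, Z992]
  moderate_severe_liver_disease: [I850, I859, I864, I982, K704, K711, K721,
                                  K729, K765, K766, K767]
  aids: [B20, B21, B22, B24]
  # Hypertensive heart (I11.0, I13.0/2) and hypertensive renal (I12.0, I13.1)
  # codes already belong to CHF / renal disease above, so the added
  # hypertension condition keeps only essential and secondary hypertension.
  hypertension: [I10, I15]
# Optional 16th condition, off by default.
optional_conditions:
  connective_tissue_disease: [M05, M06, M315, M32, M33, M34, M351, M353, M360]
# Severity hierarchies: a patient positive for both members counts only for
# the severe one.
hierarchies:
  - [mild_liver_disease, moderate_severe_liver_disease]
  - [diabetes, diabetes_with_complications]
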