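name: iii
proportional: true
effects:
- - gender_male
  - linear
- - race_chinese
  - linear
- - race_african_american
  - linear
- - race_hispanic
  - linear
- - smoker_former
  - linear
- - smoker_current
  - linear
- - diabetes
  - linear
- - sbp
  - linear
- - dbp
  - linear
- - age
  - smooth
- - bmi
  - smooth
- - ldl
  - smooth
- - hdl
  - smooth
basis_dim: 10
degree: 3
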