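analyte,standard_unit,plausible_low,plausible_high
creatinine,mg/dL,0.2,20
hemoglobin,g/dL,3,22
potassium,mmol/L,1.5,10
bmi,kg/m2,10,70
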