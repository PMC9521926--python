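analyte,unit,synonyms,factor,offset
creatinine,mg/dL,mg/dl|MG/DL|mg per dl|mg/100mL,1.0,0.0
creatinine,umol/L,μmol/L|µmol/L|umol/l|micromol/L|UMOL/L,0.011309658448314861,0.0
creatinine,mmol/L,mmol/l|mmol|MMOL/L,11.309658448314861,0.0
creatinine,mol/L,mol/l,11309.65844831486,0.0
creatinine,mg/L,mg/l,0.1,0.0
creatinine,g/L,g/l,100.0,0.0
hemoglobin,g/dL,g/dl|G/DL|gm/dl|g per dl,1.0,0.0
hemoglobin,g/L,g/l|G/L|gm/l,0.1,0.0
hemoglobin,mmol/L,mmol/l,1.61139,0.0
potassium,mmol/L,mmol/l|MMOL/L,1.0,0.0
potassium,mEq/L,meq/l|MEQ/L|mequiv/L,1.0,0.0
potassium,mg/dL,mg/dl,0.255775,0.0
bmi,kg/m2,kg/m^2|kg/m²|KG/M2,1.0,0.0
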