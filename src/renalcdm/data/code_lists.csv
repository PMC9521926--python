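coding_system,code,entity_label,entity_type,applicable_sources
ICD10,N18.2,ckd stage 2,diagnosis,
ICD10,N18.31,ckd stage 3a,diagnosis,
ICD10,N18.32,ckd stage 3b,diagnosis,
ICD10,N18.4,ckd stage 4,diagnosis,
ICD10,N18.5,ckd stage 5,diagnosis,
ICD10,N18.6,kidney failure,diagnosis,
ICD9,585.2,ckd stage 2,diagnosis,
ICD9,585.3,ckd stage 3a,diagnosis,
ICD9,585.4,ckd stage 4,diagnosis,
ICD9,585.5,ckd stage 5,diagnosis,
ICD9,585.6,kidney failure,diagnosis,
READ,1Z11.,ckd stage 2,diagnosis,
READ,1Z12.,ckd stage 3a,diagnosis,
READ,1Z13.,ckd stage 3b,diagnosis,
READ,1Z14.,ckd stage 4,diagnosis,
READ,1Z15.,ckd stage 5,diagnosis,
READ,1Z16.,kidney failure,diagnosis,
ICD10,E11.34,type 2 diabetes,diagnosis,
ICD10,E11.9,type 2 diabetes,diagnosis,
ICD9,250.00,type 2 diabetes,diagnosis,
READ,C100112,type 2 diabetes,diagnosis,
ICD10,I10,hypertension,diagnosis,
ICD9,401.9,hypertension,diagnosis,
READ,G20..,hypertension,diagnosis,
ICD10,I50.9,heart failure,diagnosis,
ICD9,428.0,heart failure,diagnosis,
READ,G58..,heart failure,diagnosis,
CPT,90935,hemodialysis,procedure,
CPT,90945,peritoneal dialysis,procedure,
ICD9,39.95,hemodialysis,procedure,
ICD9,54.98,peritoneal dialysis,procedure,
OPCS4,X40.1,hemodialysis,procedure,
OPCS4,X40.4,peritoneal dialysis,procedure,
LOCAL:jp_registry,HD001,hemodialysis,procedure,jp_registry
LOCAL:jp_registry,PD001,peritoneal dialysis,procedure,jp_registry
LOCAL:jp_registry,CHD01,chronic hemodialysis,procedure,jp_registry
LOCAL:us_claims,RX-ACE1,ace inhibitor,prescription,us_claims
LOCAL:us_claims,RX-SGLT2,sglt2 inhibitor,prescription,us_claims
LOCAL:uk_ehr,d00231,ace inhibitor,prescription,uk_ehr
LOCAL:uk_ehr,d00754,sglt2 inhibitor,prescription,uk_ehr
LOCAL:jp_registry,YJ-ACE,ace inhibitor,prescription,jp_registry
LOCAL:jp_registry,YJ-SGLT,sglt2 inhibitor,prescription,jp_registry
LOCAL:lc_panel,P-ACE,ace inhibitor,prescription,lc_panel
LOCAL:lc_panel,P-SGLT,sglt2 inhibitor,prescription,lc_panel
LOCAL:us_claims,LAB-CR,creatinine,laboratory,us_claims
LOCAL:us_claims,LAB-HB,hemoglobin,laboratory,us_claims
LOCAL:us_claims,LAB-K,potassium,laboratory,us_claims
LOCAL:us_claims,LAB-BMI,bmi,laboratory,us_claims
LOCAL:uk_ehr,44J3.,creatinine,laboratory,uk_ehr
LOCAL:uk_ehr,423..,hemoglobin,laboratory,uk_ehr
LOCAL:uk_ehr,44I4.,potassium,laboratory,uk_ehr
LOCAL:uk_ehr,22K..,bmi,laboratory,uk_ehr
LOCAL:jp_registry,L-CRE,creatinine,laboratory,jp_registry
LOCAL:jp_registry,L-HGB,hemoglobin,laboratory,jp_registry
LOCAL:jp_registry,L-POT,potassium,laboratory,jp_registry
LOCAL:jp_registry,L-BMI,bmi,laboratory,jp_registry
LOCAL:lc_panel,CRE,creatinine,laboratory,lc_panel
LOCAL:lc_panel,HGB,hemoglobin,laboratory,lc_panel
LOCAL:lc_panel,POT,potassium,laboratory,lc_panel
LOCAL:lc_panel,BMI,bmi,laboratory,lc_panel
ICD10,Z49.31,dialysis status encounter,observation,
ICD10,N17.9,acute kidney injury,outcome,
ICD9,584.9,acute kidney injury,outcome,
READ,K04..,acute kidney injury,outcome,
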