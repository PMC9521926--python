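equation,parameter,value
CKD_EPI_NO_RACE,intercept,141
CKD_EPI_NO_RACE,kappa_female,0.7
CKD_EPI_NO_RACE,kappa_male,0.9
CKD_EPI_NO_RACE,alpha_female,-0.329
CKD_EPI_NO_RACE,alpha_male,-0.411
CKD_EPI_NO_RACE,max_exponent,-1.209
CKD_EPI_NO_RACE,age_base,0.993
CKD_EPI_NO_RACE,female_multiplier,1.018
CKD_EPI_2021,intercept,142
CKD_EPI_2021,kappa_female,0.7
CKD_EPI_2021,kappa_male,0.9
CKD_EPI_2021,alpha_female,-0.241
CKD_EPI_2021,alpha_male,-0.302
CKD_EPI_2021,max_exponent,-1.2
CKD_EPI_2021,age_base,0.9938
CKD_EPI_2021,female_multiplier,1.012
MATSUO,scale,194
MATSUO,scr_exponent,-1.094
MATSUO,age_exponent,-0.287
MATSUO,female_multiplier,0.739
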