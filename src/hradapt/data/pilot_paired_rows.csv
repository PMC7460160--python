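label,mean_diff,sd_diff,n,se,ci_lower,ci_upper,t,df,p
HrateP1UAS-HrateP1CIS,16.09,4.88,3,2.82,3.98,28.21,5.72,2,0.029
HrateP2UAS-HrateP2CIS,6.60,1.88,3,1.08,1.94,11.27,6.09,2,0.026
HrateP3UAS-HrateP3CIS,22.03,8.80,3,5.08,0.17,43.88,4.34,2,0.049
Gcalorico1UAS-Gcalorico1CIS,4.67,1.53,3,0.88,0.87,8.46,5.29,2,0.034
Gcalorico2UAS-Gcalorico2CIS,1.67,0.58,3,0.33,0.23,3.10,5.00,2,0.038
Gcalorico3UAS-Gcalorico3CIS,6.33,2.31,3,1.33,0.60,12.07,4.75,2,0.042
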