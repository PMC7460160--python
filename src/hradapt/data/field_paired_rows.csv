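label,mean_diff,sd_diff,n,se,ci_lower,ci_upper,t,df,p
HrateP1UAS-HrateP1CIS,2.51,13.25,29,2.46,-2.53,7.55,1.02,28,0.316
HrateP2UAS-HrateP2CIS,4.89,10.51,29,1.95,0.90,8.89,2.51,28,0.018
HrateP3UAS-HrateP3CIS,0.96,19.19,29,3.56,-6.34,8.25,0.27,28,0.790
Gcalorico1UAS-Gcalorico1CIS,2.48,6.12,29,1.14,0.15,4.81,2.18,28,0.037
Gcalorico2UAS-Gcalorico2CIS,2.00,6.25,29,1.16,-0.38,4.38,1.72,28,0.096
Gcalorico3UAS-Gcalorico3CIS,1.72,6.28,29,1.17,-0.67,4.11,1.48,28,0.151
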