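subject,ig_mean,ig_sd,cv_pct,pt_below_70,pt_70_180,pt_above_180,severe_hypo_events,total_insulin_u,max_insulin_u,initial_weight_g,final_weight_g
DR1,113.45,39.52,34.84,6.13,87.73,6.13,0,15.85,0.11,402.6,397.2
DR2,110.97,38.17,34.39,9.72,84.72,5.56,1,12.64,0.13,402.3,383.5
DR3,100.18,34.49,34.43,18.52,77.78,3.70,3,50.16,0.86,373.9,386.0
DR4,110.26,43.38,39.34,15.63,76.39,7.99,5,21.46,0.19,437.0,409.0
DR5,126.08,42.79,33.94,10.07,78.47,11.46,0,31.24,0.32,397.0,355.6
DR6,117.30,39.16,33.38,7.87,84.95,7.18,0,23.70,1.50,454.7,451.1
DR7,117.18,33.51,28.60,4.40,91.55,4.05,0,25.06,0.77,380.5,415.3
DR8,110.94,42.70,38.49,12.27,78.59,9.14,1,49.75,1.26,453.8,390.0
DR9,128.75,33.13,25.74,3.36,90.39,6.25,0,41.19,1.50,473.3,464.7
DR10,119.74,38.53,32.18,10.42,85.19,4.40,2,23.79,0.77,457.0,442.0
DR11,137.66,35.32,25.65,5.79,87.27,6.94,1,40.15,0.65,484.0,465.9
DR12,114.50,40.30,35.20,9.14,81.71,9.14,0,34.28,1.50,392.4,404.3
DR13,99.61,32.98,33.10,17.13,79.86,3.01,0,43.43,1.01,387.1,434.0
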