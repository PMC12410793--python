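subject,p0,p1,p2,p4
DR1,2.48,0.01,368.12,4.95
DR2,0.98,0.01,425.84,2.47
DR3,11.14,0.02,1439.53,6.23
DR4,7.11,0.02,543.48,3.61
DR5,9.21,0.03,802.50,4.29
DR6,7.84,0.02,732.32,8.87
DR7,1.73,0.00,1080.85,6.75
DR8,2.05,0.01,318.11,6.09
DR9,6.39,0.02,390.04,10.49
DR10,8.64,0.02,810.89,6.06
DR11,0.85,0.00,473.25,5.12
DR12,6.94,0.01,247.05,7.73
DR13,13.50,0.04,328.73,9.25
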