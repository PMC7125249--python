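molecule_id,logP_exp,dry_1par,wet_1par,dry_2par,wet_2par
SM02,4.09,3.74,3.66,4.56,4.19
SM04,3.98,2.97,3.00,4.08,3.86
SM07,3.21,2.60,2.65,3.62,3.46
SM08,3.10,1.55,1.62,3.78,3.37
SM09,3.03,2.23,2.31,3.41,3.22
SM11,2.10,0.22,0.29,2.25,2.01
SM12,3.83,3.19,3.15,4.25,3.92
SM13,2.92,1.99,2.22,3.28,3.22
SM14,1.95,0.05,0.18,1.51,1.42
SM15,3.07,0.42,0.51,1.85,1.71
SM16,2.62,1.64,1.65,3.00,2.73
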