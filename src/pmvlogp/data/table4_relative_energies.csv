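microstate,water,octanol_wet_2par,octanol_dry_2par,octanol_wet_1par,octanol_dry_1par
SM02_micro002,0.00,0.00,0.00,0.00,0.00
SM02_micro003,5.16,5.57,5.66,5.65,5.71
SM02_micro007,6.18,8.86,8.80,10.30,10.40
SM04_micro003,0.00,0.00,0.00,0.00,0.00
SM04_micro004,8.45,9.81,9.74,10.68,10.76
SM04_micro009,11.10,11.72,11.78,12.15,12.24
SM07_micro002,8.97,10.59,10.61,11.63,11.78
SM07_micro003,6.75,7.97,8.00,8.34,8.41
SM07_micro004,0.00,0.00,0.00,0.00,0.00
SM08_micro008,10.26,24.63,24.61,32.59,33.52
SM08_micro010,5.69,6.05,6.56,4.70,4.89
SM08_micro011,0.00,0.00,0.00,0.00,0.00
SM09_micro002,6.79,9.55,9.45,11.45,11.57
SM09_micro003,0.00,0.00,0.00,0.00,0.00
SM09_micro011,5.60,6.02,6.09,6.46,6.55
SM11_micro005,0.00,0.00,0.00,0.00,0.00
SM11_micro028,7.14,8.07,8.21,8.46,8.61
SM11_micro029,14.81,17.69,17.68,18.81,18.93
SM11_micro030,26.91,34.04,34.12,36.10,36.40
SM12_micro002,4.73,5.21,5.32,5.35,5.43
SM12_micro011,5.76,8.48,8.42,10.04,10.14
SM12_micro012,0.00,0.00,0.00,0.00,0.00
SM13_micro005,0.00,0.00,0.00,0.00,0.00
SM13_micro007,6.23,6.28,6.31,6.69,6.76
SM13_micro009,8.01,10.72,10.51,12.78,12.84
SM14_micro001,0.00,0.00,0.00,0.00,0.00
SM14_micro005,28.76,37.41,37.02,41.99,42.23
SM15_micro001,9.24,19.80,18.80,26.68,26.76
SM15_micro002,0.00,0.00,0.00,0.00,0.00
SM16_micro002,0.00,0.00,0.00,0.00,0.00
SM16_micro003,12.41,13.39,13.61,12.68,12.79
SM16_micro007,6.75,11.48,11.49,13.61,13.93
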