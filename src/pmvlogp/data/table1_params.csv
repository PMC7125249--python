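solvent,model,rmse,mae,mean_signed_error,slope,intercept,r_squared,c_mu,c_V,c_q
water,all,2.04,1.43,-0.26,1.00,-0.35,1.00,,-0.10251,-15.728
water,neutrals,1.56,1.13,-0.36,0.97,-0.47,0.89,,,
water,anions,3.07,2.46,0.01,1.10,7.18,0.94,,,
water,cations,2.98,2.10,0.02,0.96,-2.62,0.85,,,
octanol_dry,1-par,1.78,1.33,0.03,0.66,-2.15,0.85,,-0.00799,
octanol_dry,2-par,1.48,1.14,-0.08,0.89,-0.78,0.87,1.33446,-0.00609,
octanol_wet,1-par,1.73,1.31,-0.01,0.68,-2.08,0.85,,-0.01552,
octanol_wet,2-par,1.51,1.16,-0.10,0.87,-0.93,0.86,1.28924,-0.01315,
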