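crop,slope,intercept,val_r2,val_rmse_pct,val_nse,val_mbe_pct,cv_r2,cv_rmse_pct,cv_nse,cv_mbe_pct
maize,44.265,11.147,0.70,9.6,0.62,-6.2,0.74,10.8,0.62,2.4
carrot,87.223,5.686,0.67,10.2,0.69,2.9,0.72,9.4,0.46,-1.6
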