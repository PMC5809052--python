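field_id,crop,ece_shallow_mean,ece_shallow_sd,ece_deep_mean,ece_deep_sd,ecw_mean,ecw_sd,deep_depth
TE-2,maize,5.21,1.26,5.16,1.41,1.81,0.30,1 m
TE-9,maize,2.34,0.33,2.38,0.41,2.04,0.33,1 m
TE-11,maize,4.27,1.49,3.86,0.61,2.09,0.08,1 m
PAL,maize,2.27,0.48,2.44,0.28,1.86,0.09,1 m
3-5N,carrot,1.77,0.21,2.61,0.74,1.63,0.21,20 cm
3-5S,carrot,1.43,0.33,2.39,0.67,1.48,0.33,20 cm
5-5N,carrot,1.76,0.73,2.28,0.67,1.56,0.26,20 cm
5-5S,carrot,2.76,1.11,2.54,0.73,1.71,0.04,20 cm
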