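crop,season,len_ini,kc_ini,len_dev,kc_dev,len_mid,kc_mid,len_late,kc_late,total
carrot,winter,20,0.45,30,0.80,40,1.10,20,0.95,110
carrot,summer,30,0.45,40,0.80,60,1.10,20,0.95,140
maize,spring,25,0.45,40,0.80,40,1.15,15,1.00,120
maize,summer,20,0.45,35,0.80,40,1.15,30,1.00,125
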