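crop,field_id,yield_t_ha,wf_green,wf_blue,wf_grey,wf_total,yp_t_ha,wf_rs_blue
maize,TE-11,29.59,30.08,2805,710,3545,28.70,2526
maize,PAL,28.32,0,3717,1243,4960,31.71,3822
maize,TE-2,25.37,0,3300,430,3730,40.68,2635
maize,TE-9,26.07,0,2593,1227,3820,26.83,2553
carrot,3-5N,40.11,0,211,86,297,45.60,257
carrot,3-5S,26.95,2.48,197,190,390,31.68,242
carrot,5-5N,42.85,0,344,159,503,44.69,300
carrot,5-5S,20.68,0,309,88,397,28.63,302
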