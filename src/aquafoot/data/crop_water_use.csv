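crop,field_id,applied_water_mm,l_leached,cwu_green_mm,cwu_blue_mm,cwu_grey_mm,cwu_total_mm,rs_cwu_blue_mm
maize,TE-11,1232,0.16,9,830,210,1049,725
maize,PAL,1688,0.28,0,1053,352,1405,1212
maize,TE-2,1072,0.11,0,837,109,946,1072
maize,TE-9,1098,0.30,0,676,320,996,685
carrot,3-5N,1775,0.20,0,1037,420,1457,1172
carrot,3-5S,836,0.47,5,374,360,739,768
carrot,5-5N,2684,0.32,0,1473,680,2153,1341
carrot,5-5S,1048,0.32,0,638,182,820,865
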