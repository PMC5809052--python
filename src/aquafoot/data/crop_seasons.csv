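crop,field_id,season,sowing,harvest,lgp_days,lr_mm,cwr_mm,cwr_plus_lr_mm
maize,TE-11,spring,2016-04-07,2016-06-27,80,159,1304,1463
maize,PAL,spring,2016-04-10,2016-06-29,80,318,1304,1622
maize,TE-2,summer,2016-07-26,2016-10-25,90,92,1140,1232
maize,TE-9,summer,2016-07-26,2016-10-25,90,287,1072,1359
carrot,3-5N,summer,2016-05-02,2016-09-08,130,732,2511,3243
carrot,3-5S,winter,2016-10-03,2016-12-24,90,307,620,927
carrot,5-5N,summer,2016-06-22,2016-10-30,140,620,2169,2788
carrot,5-5S,winter,2015-12-24,2016-03-18,85,135,823,958
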