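year,month,tmin_c,tmax_c,tmean_c,rain_mm,u2_ms,eto_mm_month,eto_mm_day
2015,12,12.2,22.8,17.6,0.0,2.8,192,6.9
2016,1,11.6,22.9,17.3,0.0,3.6,170,5.7
2016,2,13.0,25.3,19.0,0.0,4.2,234,7.8
2016,3,18.8,30.7,24.8,0.0,3.8,341,11.4
2016,4,21.1,33.9,27.5,8.9,7.9,336,11.2
2016,5,27.9,42.1,35.0,0.0,6.8,483,16.1
2016,6,29.2,45.6,37.4,0.0,7.2,496,16.5
2016,7,28.2,46.0,37.1,0.0,6.7,530,17.7
2016,8,25.6,44.6,35.2,0.0,5.9,506,16.9
2016,9,22.9,41.9,32.4,0.0,4.8,392,13.1
2016,10,16.1,34.9,25.2,0.0,3.2,246,8.2
2016,11,12.5,27.1,18.7,4.7,4.6,155,5.2
2016,12,12.0,24.6,17.1,0.0,3.8,189,6.3
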