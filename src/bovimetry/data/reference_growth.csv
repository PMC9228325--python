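stage,months,age_days,age_sd,bw_kg,bw_sd,bsa_m2,bsa_sd,volume_m3,volume_sd,wh_mm,wh_sd,cd_mm,cd_sd,hg_mm,hg_sd,kw_mm,kw_sd
month02,2,62.0,11.8,84.5,16.8,2.73,0.24,0.12,0.01,903.0,42.9,423.8,13.9,1122.3,43.5,205.5,13.5
month04,4,136.4,13.0,173.6,30.3,3.84,0.57,0.25,0.05,1118.8,47.3,543.1,19.9,1406.6,41.5,283.4,27.7
month06,6,171.0,9.6,227.5,49.5,4.16,0.56,0.28,0.06,1167.1,58.3,585.0,31.0,1517.3,104.3,299.5,15.3
month08,8,246.8,8.8,228.0,13.0,4.45,0.29,0.28,0.02,1159.1,55.7,588.9,14.7,1518.5,51.3,343.1,15.4
month12,12,369.2,8.6,366.8,47.2,5.21,0.32,0.43,0.05,1335.3,58.9,718.1,27.3,1881.2,37.1,403.2,28.9
month15,15,455.8,19.3,393.8,20.6,5.48,0.23,0.49,0.04,1405.1,49.2,743.1,45.4,2018.1,42.5,424.6,23.1
month20,20,604.8,6.3,543.4,42.5,6.37,0.62,0.61,0.06,1431.1,39.4,786.1,17.9,2085.5,101.6,508.6,11.8
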