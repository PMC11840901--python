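community,n,age_median,age_q1,age_q3,bmi_median,bmi_q1,bmi_q3,overweight_pct,scib_median,scib_q1,scib_q3,disc_lt0_pct,disc_eq0_pct,disc_gt0_pct,pal_low_pct,tdei_median,tdei_q1,tdei_q3,bmr_median,bmr_q1,bmr_q3
community_1,155,10,9,11,18.8,16.7,21.8,46.5,18.7,16.9,20.9,14.2,61.9,23.9,69.0,2033.7,1840.9,2273.0,1328.9,1213.8,1455.9
community_2,208,11,9,12,18.5,16.7,21.5,44.2,18.0,16.6,20.5,14.9,56.7,28.4,63.5,2055.2,1870.7,2332.7,1330.3,1199.8,1466.1
community_3,43,11,9.5,11,18.1,16.2,21.0,37.2,18.3,16.2,20.3,7.0,81.4,11.6,76.7,1955.5,1756.7,2123.2,1275.8,1192.2,1440.8
community_4,156,10,9,11,18.4,17.2,21.4,41.0,18.3,17.2,20.1,14.7,60.9,24.4,67.9,2002.1,1798.5,2301.9,1307.2,1200.7,1466.2
community_5,201,10,9,11,18.1,16.4,21.1,39.8,18.1,16.6,20.1,18.4,55.2,26.4,69.7,1956.0,1780.8,2204.3,1297.9,1186.1,1412.5
community_6,322,10,9,11,18.2,16.5,20.5,38.5,18.1,16.5,19.9,14.3,65.2,20.5,59.6,2031.1,1804.8,2248.4,1280.2,1187.7,1410.6
pooled,1085,10,9,11,18.4,16.6,21.2,41.3,18.1,16.7,20.2,14.9,61.3,23.8,65.4,2010.6,1814.2,2274.0,1305.6,1192.9,1434.1
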