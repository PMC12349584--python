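infant_id,ga_weeks,weight_g,position,avg_active_sensors,err_ll_pct,err_rl_pct,err_la_pct,err_ra_pct,err_still_pct
1,31.6,1560,supine,3.23,6.67,0.00,32.86,-9.57,-33.14
2,27.3,1440,lateral,4.81,6.67,0.00,0.00,3.33,0.10
3,30.7,1990,supine,9.11,-0.67,0.00,-25.67,-39.00,15.00
4,36.1,1810,lateral,5.71,0.00,0.00,13.33,-6.79,-23.15
5,33.6,1985,supine,3.75,-43.85,-39.23,-27.44,-19.74,47.61
6,32.7,2190,lateral,8.36,-7.27,0.00,-13.38,5.00,-7.50
7,33.1,2230,lateral,12.00,6.67,3.33,-15.28,-0.83,10.83
8,33.1,2310,supine,5.11,0.00,3.33,-2.00,0.00,-0.33
10,32.3,1150,lateral,9.91,3.33,2.50,-29.20,-11.94,13.86
11,27.1,2500,prone,6.19,0.00,0.00,-20.83,1.39,-9.79
12,27.1,2725,supine,8.91,0.00,0.00,-1.67,-43.33,-4.72
13,25.3,1380,lateral,9.88,26.67,-0.74,0.00,-6.30,-25.56
14,26.0,1830,supine,8.50,-1.82,-1.82,-35.45,0.61,-3.03
16,28.7,1230,supine,10.88,3.33,0.00,0.00,0.00,9.63
17,28.7,1100,lateral,14.89,0.00,26.67,0.00,0.00,-20.33
18,30.3,1670,lateral,15.36,29.10,0.00,-41.60,-28.48,-7.91
20,29.5,1395,lateral,13.30,0.00,0.00,-58.35,3.38,19.74
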