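site,area_ha,total_oc_stock_tons,belowground_oc_stock_tons,sar_lower_mm_yr,sar_upper_mm_yr,burial_lower_g_m2_yr,burial_upper_g_m2_yr,total_burial_t_yr
Bahia Samborombon,39710,1100351,973364,0.96,1.16,37.84,29.90,12274.54
Mar Chiquita,3882,130974,120529,,,,,
Bahia Blanca,29634,1414699,1379077,1.03,0.65,28.60,18.23,8467.23
Bahia Anegada,62563,1000852,989922,0.66,1.24,8.45,56.21,27007.98
Rio Negro,703,36434,29523,3.44,1.51,204.21,65.90,528.28
Caleta Los Loros,470,4477,4126,0.67,0.62,7.38,10.30,35.55
Bahia San Antonio,4192,175814,167761,0.63,2.86,15.32,58.36,1556.31
Playas Doradas,30,1481,1432,0.80,0.58,31.53,13.14,9.39
Riacho San Jose,356,13224,12638,0.53,0.95,22.91,11.02,52.08
Puerto San Julian,1369,70630,69209,1.48,0.86,76.59,50.25,1048.54
Punta Loyola,2400,187557,180912,0.84,1.63,34.56,171.67,4120.20
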