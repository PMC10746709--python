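site,species,core_depth_cm,burrow_abundance,burrow_diameter_cm,biomass_roots,biomass_green,biomass_senescent,stock_roots,stock_green,stock_senescent,stock_belowground,stock_total
Bahia Samborombon,Sa,74.4,4,1.5,2099.4,207.3,72.4,5.18,0.81,0.20,32.81,33.82
Bahia Samborombon,Sd,49.4,4.4,1.9,1215.5,913.5,848.6,3.64,3.85,3.45,37.79,45.10
Bahia Samborombon,Ssp,56.8,6.8,1.7,729.3,586,59.3,1.84,2.08,0.23,18.71,21.02
Mar Chiquita,Sd,79.4,6.6,2.1,1107,363.3,292.2,3.90,1.55,1.14,31.05,33.74
Bahia Blanca,Sa,100,5,20.4,3931.5,317.3,66,10.81,1.18,0.22,58.62,60.03
Bahia Blanca,Sd,100,13.8,2.1,1505,542.9,253.5,4.38,2.19,0.99,42.67,45.85
Bahia Blanca,Ssp,100,1.6,1.8,126.5,324.2,3.5,0.38,1.09,0.01,41.10,42.20
Bahia Anegada,Sa,50,0.2,4.7,461.1,45.5,9.3,1.56,0.16,0.02,17.08,17.26
Bahia Anegada,Ssp,50,0,,245.7,71.7,11.7,0.83,0.14,0.04,15.21,15.38
Bahia San Antonio,Sa,50,7,1.9,780.1,436.6,236.2,2.29,1.54,0.80,36.64,38.98
Bahia San Antonio,Ssp,36,0.2,2,170.9,444,43.3,0.62,1.35,0.16,43.31,44.82
Rio Negro,Sa,100,12.7,1.6,10276.2,470.7,294.1,33.88,1.54,1.04,82.91,85.5
Rio Negro,Sd,39.3,1.7,1.4,1620.6,1365.9,1187,0.66,5.71,4.64,39.06,49.41
Caleta Los Loros,Sa,50,3.6,2.6,1458.6,195.5,65.8,33.79,0.61,0.14,8.99,9.73
Caleta Los Loros,Ssp,50,0,,61.7,262.2,3,0.19,0.71,0.01,5.74,6.47
Playas Doradas,Ssp,64.6,10,1.9,117.7,542.2,0,0.36,1.65,0,48.09,49.74
Riacho San Jose,Sa,100,13.6,2.3,9770.2,406.2,270.6,29.04,1.73,0.92,108.81,111.92
Riacho San Jose,Sd,55,0,,661.2,1279,1526.7,2.37,5.15,5.66,38.57,49.38
Puerto San Julian,Ssp,72,0,,4530.4,378.9,0.44,14.9,1.04,0.02,50.55,51.59
Punta Loyola,Ssp,67.6,0,,11809.9,990.7,18.44,31.88,2.74,0.03,75.38,78.14
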