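center_cm1,center_sd_pct,fwhm_cm1,fwhm_sd_pct,area_dna_rna,area_protein,area_lipid
3300,1.8,308,1,4.000,3.000,1.800
2962,0.7,15,1,0.010,0.010,0.030
2920,0.6,19,1,0.030,0.060,0.080
2850,0.6,23,1,0.030,0.040,0.070
2352,0.4,27,,0.100,0.100,0.100
1754,0.3,19,1,0.020,0.010,0.070
1650,0.5,42,1,0.400,1.000,0.300
1550,0.4,39,1,0.300,0.600,0.200
1462,0.3,23,1,0.040,0.120,0.080
1400,0.2,23,1,0.100,0.037,0.060
1342,0.2,19,1,0.045,0.032,0.050
1280,0.2,27,1,0.060,0.050,0.010
1242,0.2,39,1,0.100,0.040,0.020
1172,0.2,19,1,0.012,0.020,0.040
1080,0.2,39,1,0.100,0.020,0.015
1030,0.2,35,1,0.120,0.035,0.020
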