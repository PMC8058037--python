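state,alcohol_tax,sales_tax,gas_tax,cigarette_tax,poverty_thousands,heavy_drinking_pct,urban_pct,population_thousands,impaired_driving_death_rate
AL,1.2,4.33,37.5,0.46,655.0,6.32,81.1,12513.0,2.82
AK,0.59,5.99,30.6,3.09,2542.0,8.95,66.9,5945.0,5.32
AZ,1.18,2.93,46.0,1.65,1313.0,8.19,45.8,7996.0,5.57
AR,1.06,7.01,23.2,3.3,889.0,5.66,77.9,7653.0,2.62
CA,0.71,3.65,24.7,3.73,4117.0,7.3,77.9,10696.0,3.21
CO,2.14,0.93,24.1,0.91,1269.0,7.92,67.2,1655.0,5.17
CT,1.79,7.82,29.6,3.44,449.0,4.57,64.0,1682.0,2.41
DE,1.28,3.65,11.4,1.74,2012.0,8.91,49.4,16237.0,6.03
DC,1.12,6.02,28.1,1.73,1104.0,5.31,65.1,7475.0,2.0
FL,0.45,0.63,22.7,2.82,3620.0,4.31,57.0,2245.0,2.96
GA,1.59,6.47,19.7,4.1,3143.0,8.66,54.7,9772.0,6.28
HI,1.36,1.22,19.9,2.93,4795.0,7.14,71.3,15310.0,4.22
ID,2.28,1.0,41.9,1.08,4307.0,7.15,75.0,8669.0,4.7
IL,2.43,2.21,25.4,0.2,1581.0,8.77,88.9,9253.0,3.74
IN,2.06,3.4,49.2,0.65,4355.0,8.33,84.7,7407.0,3.81
IA,2.19,3.88,26.5,1.38,1315.0,8.3,73.1,9336.0,5.58
KS,1.34,3.43,37.9,0.48,4317.0,8.38,74.1,9012.0,4.17
KY,1.06,0.28,22.2,0.47,775.0,5.15,58.7,3846.0,2.69
LA,1.3,4.78,43.1,3.99,4693.0,3.8,48.5,1039.0,2.86
ME,1.42,5.94,18.5,0.81,2872.0,5.34,74.2,7134.0,4.1
MD,2.08,7.83,21.0,1.54,2337.0,5.08,33.0,21594.0,1.96
MA,0.55,4.43,21.7,4.06,2065.0,5.35,68.8,9816.0,2.23
MI,1.58,7.45,15.2,2.33,1937.0,4.96,87.8,8129.0,2.52
MN,2.28,7.62,40.0,2.97,836.0,8.2,72.3,11421.0,5.17
MS,0.71,1.7,27.3,1.35,3206.0,5.75,82.8,9156.0,2.08
MO,0.86,0.53,15.0,2.86,1829.0,7.53,37.9,2044.0,5.01
MT,2.14,1.36,31.4,0.85,4452.0,6.48,51.0,23568.0,3.36
NE,1.7,5.96,29.5,1.58,668.0,9.9,44.4,13943.0,6.79
NV,2.42,2.09,30.2,3.83,2390.0,6.5,71.7,2751.0,2.43
NH,1.68,0.9,38.5,3.12,2977.0,7.69,68.1,3223.0,6.12
NJ,2.38,7.55,12.7,2.05,3695.0,9.28,97.3,6119.0,5.93
NM,2.1,5.47,29.7,2.03,3326.0,8.78,75.1,9613.0,6.85
NY,1.75,7.67,12.1,3.17,2183.0,5.63,46.6,1853.0,2.3
NC,0.64,2.64,49.0,1.79,3708.0,7.04,76.8,6869.0,2.51
ND,0.69,1.54,36.4,1.93,3600.0,9.05,92.1,9698.0,6.07
OH,2.18,1.09,16.8,2.47,1958.0,8.48,60.5,4517.0,4.77
OK,0.97,7.55,46.8,2.44,2190.0,10.07,69.2,1377.0,8.43
OR,1.78,1.31,17.0,2.04,1823.0,8.6,44.8,12145.0,5.7
PA,1.2,6.42,24.2,2.62,3938.0,8.98,17.9,1658.0,5.4
RI,1.26,1.69,11.9,0.8,765.0,5.93,72.5,1240.0,3.12
SC,0.22,6.9,24.9,3.16,4128.0,8.59,70.8,7548.0,5.08
SD,2.09,0.45,39.3,0.85,2991.0,9.37,59.4,10525.0,5.98
TN,0.92,3.05,14.9,3.43,1906.0,8.24,49.9,12439.0,4.95
TX,0.98,3.22,41.1,2.49,4762.0,5.72,61.9,3041.0,2.24
UT,0.36,7.81,27.1,3.94,4839.0,8.16,65.9,9630.0,2.75
VT,1.64,7.18,42.1,1.87,4893.0,10.28,91.3,6029.0,5.3
VA,1.99,3.08,17.0,2.83,555.0,8.26,63.1,2229.0,6.08
WA,1.38,3.4,46.1,0.49,2503.0,6.68,67.1,14379.0,4.69
WV,1.3,5.72,39.1,1.41,4654.0,9.65,79.5,5107.0,6.63
WI,1.98,5.12,11.9,0.85,94.0,4.36,44.5,4370.0,1.59
WY,0.42,7.15,29.2,2.87,1550.0,6.15,67.3,12049.0,2.99
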