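site,lat,lon,S,temp_sd,turnover_mean,discharge_sd,phi,p_value
MAYF,32.96,-87.41,179,18.51,0.42,0.015,0.16,0.001
SYCA,33.75,-111.51,134,14.75,0.63,0.438,0.43,0.001
TECR,36.96,-119.03,148,1.22,0.24,0.005,0.03,0.386
BIGC,37.06,-119.26,174,13.52,0.32,0.005,0.21,0.001
COMO,40.03,-105.54,126,3.47,0.25,0.015,0.18,0.001
WLOU,39.89,-105.92,109,2.16,0.23,0.015,0.24,0.001
KING,39.11,-96.60,123,10.24,0.63,0.006,0.22,0.001
MCDI,38.95,-96.44,126,10.49,0.48,0.007,0.19,0.001
HOPB,42.47,-72.33,223,11.17,0.29,0.015,0.18,0.001
MCRA,44.26,-122.17,157,5.65,0.23,0.016,0.62,0.001
LECO,35.69,-83.50,195,13.29,0.28,0.016,0.08,0.001
WALK,35.96,-84.28,186,12.87,0.21,0.145,0.10,0.001
PRIN,33.38,-97.78,164,16.13,0.34,0.004,0.01,0.674
REDB,40.78,-111.80,142,8.57,0.27,0.098,0.29,0.001
LEWI,39.10,-77.98,132,13.33,0.31,0.006,0.20,0.003
POSE,38.89,-78.15,228,11.28,0.27,0.002,0.10,0.001
MART,45.79,-121.93,159,9.23,0.22,0.021,0.16,0.001
BLDE,44.95,-110.59,143,1.32,0.21,0.060,0.26,0.001
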