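genotype,role,seed_type,2008,2009,2010,2011,2012,2013
R63N/1,dh_line,hulled,54.04,52.81,51.00,46.91,53.39,51.16
R63N/3,dh_line,hulled,59.91,43.82,52.20,37.56,56.44,48.36
R63N/4,dh_line,hulled,57.72,41.09,48.51,38.68,49.43,49.24
R63N/9,dh_line,hulled,52.20,38.26,47.51,34.63,42.49,51.03
R63N/18,dh_line,hulled,61.46,50.82,51.95,36.21,48.78,50.68
R63N/21,dh_line,hulled,56.13,50.74,53.78,42.04,58.61,56.47
R63N/22,dh_line,hulled,49.35,53.11,48.31,43.60,53.53,52.41
R63N/27,dh_line,hulled,41.54,38.48,45.35,42.96,46.21,47.60
R63N/28,dh_line,hulled,53.09,38.25,47.41,37.96,38.96,41.84
R63N/34,dh_line,hulled,50.88,41.50,49.86,37.22,51.18,50.67
R63N/35,dh_line,hulled,42.19,37.51,48.43,36.18,34.27,41.63
R63N/61,dh_line,hulled,55.29,56.65,55.70,47.35,55.04,57.52
R63N/63,dh_line,hulled,54.77,48.16,48.48,38.84,40.80,50.57
R63N/67,dh_line,hulled,53.26,33.62,51.18,38.03,44.57,51.62
R63N/74,dh_line,hulled,53.23,58.21,43.61,42.76,39.59,43.10
R63N/19,dh_line,hull_less,49.65,35.52,39.64,30.81,41.56,42.97
R63N/46,dh_line,hull_less,48.98,49.65,44.02,27.27,33.50,34.00
R63N/47,dh_line,hull_less,37.02,27.00,35.29,31.60,48.57,49.00
R63N/14,dh_line,hull_less,43.29,33.82,43.88,36.81,49.59,46.30
R63N/20,dh_line,hull_less,54.68,44.47,41.52,38.84,44.22,43.26
R63N/52,dh_line,hull_less,49.20,38.91,46.62,45.47,30.78,38.36
R63N/65,dh_line,hull_less,44.16,34.74,47.22,40.84,55.69,49.94
R63N/24,dh_line,hull_less,38.52,29.58,39.68,36.25,32.69,32.07
R63N/31,dh_line,hull_less,47.42,43.74,47.16,38.86,49.14,44.84
R63N/42,dh_line,hull_less,40.97,37.12,38.85,24.35,37.79,46.92
R63N/43,dh_line,hull_less,47.54,48.27,42.80,39.95,40.61,43.65
R63N/55,dh_line,hull_less,53.18,46.51,46.99,44.67,55.09,48.14
R63N/70,dh_line,hull_less,53.80,48.18,47.81,38.81,55.20,49.96
R63N/71,dh_line,hull_less,50.55,44.51,43.71,41.25,44.35,48.73
R63N/75,dh_line,hull_less,37.32,34.51,35.56,32.59,35.79,43.25
RK63/1,parent,hulled,46.59,44.77,46.65,42.08,49.98,54.13
1N86,parent,hull_less,43.87,40.02,38.48,39.54,39.47,38.56
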