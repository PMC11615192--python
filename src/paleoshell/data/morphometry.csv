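site_id,label,silhouette_area_mm2,silhouette_rsd_pct,potential_volume_nl,potential_rsd_pct,test_volume_nl,test_rsd_pct,biovolume_nl,biovolume_rsd_pct,outer_surface_area_mm2,outer_surface_rsd_pct,debris_pct
1,VM27-261,0.126,13,20.807,13,9.705,19,9.988,11,0.436,10,12
2,VM19-308,0.129,11,22.374,12,11.231,9,12.185,18,0.519,8,7
3,VM16-206,0.132,10,21.689,8,9.991,13,11.698,15,0.510,6,7
4,VM23-112,0.131,11,21.291,13,9.384,8,11.907,19,0.497,11,5
5,VM22-26,0.135,10,22.429,12,9.259,20,13.630,16,0.512,8,7
6,RC13-189,0.136,10,20.170,11,7.617,24,12.554,14,0.488,8,7
7,RC13-188,0.134,9,20.482,13,7.132,24,13.350,12,0.487,9,8
8,RC24-10,0.136,8,20.480,14,6.653,21,13.827,15,0.549,11,3
9,RC24-11,0.135,11,19.264,13,6.352,18,12.912,18,0.467,9,4
10,RC24-16,0.133,11,20.612,12,7.385,21,13.227,15,0.496,9,2
11,RC24-17,0.133,13,21.786,7,8.836,15,13.550,13,0.509,5,6
12,VM22-175,0.133,10,19.399,10,8.113,15,11.286,14,0.475,7,2
13,RC16-77,0.132,11,18.205,11,7.418,12,10.786,17,0.452,9,5
14,VM16-36,0.134,12,20.595,13,8.520,16,12.075,15,0.506,9,9
15,RC08-19,0.130,12,17.584,16,7.347,18,10.237,20,0.452,10,3
16,RC08-23,0.130,11,19.822,12,8.459,13,11.363,16,0.477,8,10
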