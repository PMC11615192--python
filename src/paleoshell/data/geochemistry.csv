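site_id,label,shell_weight_ug,mgca_mmol_mol,mgca_replicate_mmol_mol,temperature_c,acd_m,salinity_acd,sigma_theta_acd,co3_3d_umol_kg,salinity_3d,sigma_theta_3d
1,VM27-261,31.2,3.62,,24.0,44.3,36.9,25.12,250.3,36.6,26.0
2,VM19-308,30.2,3.80,,24.6,47.4,37.1,25.08,285.4,37.0,25.9
3,VM16-206,32.2,4.00,,25.3,71.8,37.4,25.06,289.4,37.3,25.5
4,VM23-112,32,3.64,,24.0,103.0,37.3,25.34,269.2,36.9,25.0
5,VM22-26,28.3,3.50,,23.5,69.2,36.6,24.71,285.7,36.1,24.8
6,RC13-189,27.9,3.99,,25.3,61.6,36.0,24.76,250.1,36.0,24.3
7,RC13-188,27.3,3.57,,23.8,76.9,36.0,24.50,231.1,36.0,24.8
8,RC24-10,24.1,2.92,2.80,21.1,47.3,35.8,25.10,235.8,35.9,24.2
9,RC24-11,22.1,2.92,,21.1,47.4,35.8,25.10,235.8,35.9,24.2
10,RC24-16,26.7,3.15,,22.1,66.9,36.0,24.96,251.2,35.8,24.6
11,RC24-17,25.6,3.19,,22.3,67.9,36.0,24.63,250.4,35.8,24.6
12,VM22-175,27.8,3.82,,24.7,61.6,36.4,24.51,254.6,36.5,24.4
13,RC16-77,28.8,3.53,,23.6,56.8,36.8,25.11,259.2,36.7,24.9
14,VM16-36,29.8,3.25,3.24,22.5,68.1,36.5,25.18,260.2,36.5,24.9
15,RC08-19,29.2,3.51,,23.5,51.9,36.6,24.96,258.4,36.4,24.9
16,RC08-23,31.6,3.09,3.59,21.8,63.8,36.3,25.29,252.2,36.1,25.1
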