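site_id,label,latitude,longitude,water_depth_m,core_depth_cm,age,stratigraphy
1,VM27-261,31.367,-35.983,3253,0,4.550 +/- 0.035 ka,14C
2,VM19-308,29.017,-41.4,3197,4.5,4.520 +/- 0.035 ka,14C
3,VM16-206,23.333,-46.483,3733,6.5,Holocene,iso. strat.
4,VM23-112,17.267,-46.75,2845,4.5,5.800 +/- 0.086 ka,14C
5,VM22-26,8.717,-41.25,3720,12.5,Holocene,% carbonate
6,RC13-189,1.863,-30,3233,4.5,0-2.5 kyr BP,14C strat.
7,RC13-188,1.817,-33.683,3451,2.5,4.478 +/- 0.079 ka,14C
8,RC24-10,-2.177,-11.252,3451,2.5,0-2.5 kyr BP,14C strat.
9,RC24-11,-2.183,-11.25,3445,0,2.655 +/- 0.035 ka,14C
10,RC24-16,-5.038,-10.192,3559,0,Holocene,iso. strat.
11,RC24-17,-5.05,-10.183,3559,0.5,2.635 +/- 0.035 ka,14C
12,VM22-175,-8.767,-14.283,2950,0,Holocene,% carbonate
13,RC16-77,-12.652,-13.437,3404,6.5,Holocene,iso. strat.
14,VM16-36,-19.367,-11.433,3329,13.5,0-5 kyr BP,14C strat.
15,RC08-19,-24.3,-14.7,3636,10.5,Holocene,% carbonate
16,RC08-23,-25.15,-12.767,3338,9.5,Holocene,iso. strat.
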