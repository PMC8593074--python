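individual_id,standard_length_cm,weight_kg,tag_type,deployment_date,track_duration_days,n_trips,trip_mean_days,trip_min_days,trip_max_days
64487,148,60,Standard,2019-02-20,108,22,2.4,0.1,17.4
64488,142,,Standard,2019-03-02,197,25,1.2,0.1,30.9
64490,145,,Standard,2019-02-27,124,29,0.5,0.1,23.9
64491,137,62,Standard,2019-02-21,41,15,0.4,0.1,4.5
64492,152,65,Standard,2019-02-21,42,7,3.2,0.1,13.6
64515,140,,Standard,2019-02-26,26,7,1.6,0.4,2.8
64519,146,58,Standard,2019-02-20,102,24,0.5,0.2,28.7
64520,132,,Standard,2019-02-26,49,12,1.0,0.2,7.5
64525,137,,Standard,2019-02-27,33,7,2.6,0.1,5.8
64527,141,,Standard,2019-03-05,154,22,1.6,0.1,27.4
64528,139,,Dive,2019-03-01,72,21,0.6,0.2,19.4
64537,133,,Dive,2019-03-01,84,13,2.6,0.1,36.6
64529,145,,Dive,2019-02-28,2,0,,,
64538,141,,Dive,2019-03-01,30,16,0.4,0.1,3.1
64555,128,,Dive,2019-02-28,78,23,1.5,0.1,14.4
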