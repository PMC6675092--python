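patient_id,n_nodules,min_p_diameter,min_p_volume,min_min_p,heterogeneous
1,4,0.2815,0.3005,0.2815,No
2,5,0.0966,0.4226,0.0966,No
3,7,0.0879,0.1879,0.0879,No
4,8,0.1463,0.3292,0.1463,No
5,8,0.0324,0.1955,0.0324,Yes
6,9,0.0399,0.2978,0.0399,Yes
7,10,0.0305,0.0283,0.0283,Yes
8,25,0.0273,0.1052,0.0273,Yes
9,27,0.0003,0.0002,0.0002,Yes
10,52,0.0003,0.0033,0.0003,Yes
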