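survey_id,recorded_cuff_size,arm_circ_code,mean_arm_circ_cm,min_arm_circ_cm,max_arm_circ_cm,pct_misscuffed,pct_identical_sbp_12,pct_identical_dbp_12,pct_identical_sbp_23,pct_identical_dbp_23
A,No,B,30.8,24.5,43.5,#,8,29,16,28
B,Yes,B,31.6,23.0,48.0,1,10,29,31,41
C,Yes,B,28.3,20.0,40.0,0,10,13,19,19
D,Yes,N,§,§,§,#,4,10,7,12
E,Yes,B,29.9,22.0,41.5,0,5,9,6,11
F,Yes,B,28.9,21.0,41.5,2,3,9,9,11
G,Yes,M,§,§,§,#,7,12,8,13
H,Yes,B,30.1,21.0,48.0,20,3,8,5,9
I,Yes,B,30.9,22.0,46.0,0,8,10,8,10
J,Yes,N,§,§,§,#,6,14,9,15
K,Yes,B,30.4,21.5,43.3,5,4,10,7,10
L,Yes,B,30.4,24.0,40.0,1,5,9,5,11
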