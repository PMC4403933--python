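survey_id,device,pct_digit_0,pct_digit_1,pct_digit_2,pct_digit_3,pct_digit_4,pct_digit_5,pct_digit_6,pct_digit_7,pct_digit_8,pct_digit_9,p_text
A,Mercury sphygmomanometer,21,0,19,0,26,0,18,0,16,0,0.0392
B,Mercury sphygmomanometer,35,8,8,5,7,17,6,5,6,4,<0.0001
C,Mercury sphygmomanometer,22,0,17,0,19,0,19,0,23,0,0.0317
D,Omron i-C10,15,12,9,9,8,9,10,10,8,9,0.0122
E,Omron i-C10,11,9,9,9,11,10,9,12,10,11,0.2596
F,Omron i-C10,11,10,7,10,9,12,11,10,9,10,0.4936
G,Omron M6,10,9,10,10,10,10,10,10,10,10,0.7859
H,Omron M6,9,9,10,12,10,10,10,11,10,9,0.9850
I,Other Omron models,12,12,10,11,12,9,9,9,9,8,0.1123
J,Other Omron models,11,9,10,11,9,10,10,11,10,9,0.4148
K,Other brands,11,11,10,12,9,10,8,8,9,12,0.2285
L,Other brands,11,9,11,9,11,9,9,11,11,9,0.9030
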