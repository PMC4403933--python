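survey_id,device,pct_digit_0,pct_digit_1,pct_digit_2,pct_digit_3,pct_digit_4,pct_digit_5,pct_digit_6,pct_digit_7,pct_digit_8,pct_digit_9,p_text
A,Mercury sphygmomanometer,22,0,23,0,21,0,18,0,17,0,0.4488
B,Mercury sphygmomanometer,33,6,9,3,5,22,5,4,9,4,<0.0001
C,Mercury sphygmomanometer,18,0,20,0,20,0,19,0,23,0,0.1352
D,Omron i-C10,9,11,11,9,10,11,11,9,11,9,0.9826
E,Omron i-C10,11,10,10,9,10,10,9,11,10,9,0.7936
F,Omron i-C10,12,9,11,7,11,7,6,13,15,9,0.0007
G,Omron M6,11,10,9,10,11,10,10,10,9,10,0.0464
H,Omron M6,10,8,12,8,9,11,9,13,12,8,0.2126
I,Other Omron models,10,8,12,9,11,8,9,9,11,12,0.4071
J,Other Omron models,11,10,12,10,9,9,9,10,10,10,0.1308
K,Other brands,9,11,9,12,11,10,13,7,9,9,0.1753
L,Other brands,10,10,13,10,9,10,8,9,9,11,0.5258
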