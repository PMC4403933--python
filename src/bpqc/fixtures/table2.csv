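survey_id,n_participants,survey_period,mean_temp_c,min_temp_c,max_temp_c,arm,posture,device_type,device_model,cuff_sizes,stethoscope_side
A,123,May-Jun 2011,22.3,21,24,right,sitting,mercury,Riester diplomat presometer,"22–32 cm and 33–41 cm",bell
B,111,Apr-Jul 2011,25.0,18,33,right,sitting,mercury,Riester diplomat presometer,"17–26 cm, 24–32 cm, 32–48 cm",diaphragm
C,393,Oct 2010-Jan 2011,22.8,21,26,right,sitting,mercury,Riva Rocci,"≤34 cm, > 34 cm",bell
D,183,Nov 2010-Jan 2011,23.3,22,24,right,sitting,oscillometric,Omron i-C10,"22–42 cm",not_relevant
E,305,May-Jun 2011,23.0,16,29,right,sitting,oscillometric,Omron i-C10,"22–42 cm",not_relevant
F,131,Nov 2010-Feb 2011,23.2,22,25,right,sitting,oscillometric,Omron i-C10,"22–42 cm, > 42 cm",not_relevant
G,1302,Oct-Dec 2010,#,#,#,right,sitting,oscillometric,Omron M6,"17–22 cm, 22–32 cm, 32–42 cm",not_relevant
H,137,May-Jul 2010,#,#,#,right,sitting,oscillometric,Omron M6,"22–32 cm",not_relevant
I,168,Jan-Mar 2011,21.3,16,25,right,sitting,oscillometric,Omron 705IT,"≤21 cm, 22–31 cm, ≥ 32 cm",not_relevant
J,922,Jan-May 2011,19.4,12,25,right,sitting,oscillometric,Omron HEM-907,"17–22 cm, 22–32 cm, 32–42 cm",not_relevant
K,190,Jun-Jul 2011,23.4,19,32,right,sitting,oscillometric,Datascope Accutorr Plus,"13–20 cm, 21–27 cm, 28–35 cm, 36–46 cm",not_relevant
L,162,Nov-Dec 2010,#,#,#,right,sitting,oscillometric,Citizen CH-432B,"20–26 cm, 25–34 cm, 32–43 cm",not_relevant
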