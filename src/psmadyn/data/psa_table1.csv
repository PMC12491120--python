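patient_id,day,psa_ng_ml,pet_negative
P1,0,3.4,0
P1,7,4.2,0
P1,21,3.5,0
P1,28,3.5,0
P2,0,5.2,1
P2,7,4.4,1
P2,21,2.5,1
P2,28,2.0,1
P3,0,0.9,0
P3,7,,0
P3,21,,0
P3,28,0.1,0
P4,0,59.0,0
P4,7,35.0,0
P4,21,8.4,0
P4,28,6.9,0
P5,0,17.0,0
P5,7,13.0,0
P5,21,11.0,0
P5,28,14.0,0
P6,0,9.0,0
P6,7,7.0,0
P6,21,4.0,0
P6,28,0.8,0
P7,0,27.0,0
P7,7,,0
P7,21,,0
P7,28,2.7,0
P8,0,30.0,0
P8,7,17.0,0
P8,21,13.0,0
P8,28,11.0,0
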