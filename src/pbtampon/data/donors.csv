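donor_id,age,race
RP54,51,Caucasian
RP83,46,Caucasian
RP115,22,Caucasian
RN1,28,Caucasian
RN2,25,Caucasian
RN3,24,Caucasian
RN4,26,Caucasian/Hispanic/Latinx
RN5,33,Caucasian
RN6,36,Black/African American/Caucasian
RN8,26,Caucasian
RN9,27,Caucasian
RN10,30,Caucasian
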