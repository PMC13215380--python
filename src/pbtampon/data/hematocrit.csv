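purpose,donor_id,cycle_day,cycle_month,hematocrit_pct,status
day_to_day,RP54,1,,27,ok
day_to_day,RP54,2,,25,ok
day_to_day,RP54,3,,20,ok
day_to_day,RP54,4,,24,ok
month_to_month,RP54,2,1,30,ok
month_to_month,RP54,2,2,25,ok
month_to_month,RP54,2,3,19,ok
month_to_month,RP83,2,1,52,ok
month_to_month,RP83,2,2,25,ok
month_to_month,RP83,2,3,35,ok
donor_to_donor,RP54,2,,25,ok
donor_to_donor,RP83,2,,37,ok
donor_to_donor,RP115,2,,,failed
donor_to_donor,RN1,2,,25,ok
donor_to_donor,RN2,2,,27,ok
donor_to_donor,RN3,2,,,failed
donor_to_donor,RN4,2,,20,ok
donor_to_donor,RN5,2,,24,ok
donor_to_donor,RN6,2,,25,ok
donor_to_donor,RN8,2,,36,ok
donor_to_donor,RN9,2,,16,ok
donor_to_donor,RN10,2,,17,ok
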