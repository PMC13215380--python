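purpose,spike_dose_ng_ml,donor_id,cycle_day,cycle_month,k_rbc_plasma,k_fluid_plasma
day_to_day,10,RP54,1,,73.5,20.6
day_to_day,10,RP54,2,,82.0,21.2
day_to_day,10,RP54,3,,11.2,3.0
day_to_day,10,RP54,4,,26.8,7.2
month_to_month,10,RP54,2,1,107.4,32.9
month_to_month,10,RP54,2,2,82.0,21.2
month_to_month,10,RP54,2,3,93.4,18.6
month_to_month,10,RP83,2,1,3.5,2.3
month_to_month,10,RP83,2,2,1.3,1.1
month_to_month,10,RP83,2,3,2.5,1.5
dose_response,0,RP54,2,,63.7,17.0
dose_response,1,RP54,2,,22.8,7.6
dose_response,10,RP54,2,,94.3,24.2
dose_response,25,RP54,2,,116.7,32.7
dose_response,0,RP83,2,,6.9,3.6
dose_response,1,RP83,2,,3.6,2.1
dose_response,10,RP83,2,,2.4,1.6
dose_response,25,RP83,2,,2.9,1.8
donor_to_donor,10,RP54,2,,94.3,24.2
donor_to_donor,10,RP83,2,,2.4,1.6
donor_to_donor,10,RN1,2,,3.0,1.5
donor_to_donor,10,RN2,2,,3.5,1.7
donor_to_donor,10,RN4,2,,4.4,1.7
donor_to_donor,10,RN5,2,,2.3,1.3
donor_to_donor,10,RN6,2,,1.6,1.2
donor_to_donor,10,RN8,2,,0.9,0.9
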