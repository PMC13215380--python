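purpose,donor_id,source,cycle_day,cycle_month,spike_dose_ng_ml,percent_unbound,sd,n_replicates,donor_conc,receiver_conc
day_to_day,RP54,menstrual_plasma,1,,10,1.5,0.2,3,10.0,0.15
day_to_day,RP54,menstrual_plasma,2,,10,2.0,1.5,3,10.0,0.20
month_to_month,RP83,menstrual_plasma,2,1,10,2.7,0.2,3,10.0,0.27
month_to_month,RP83,menstrual_plasma,2,2,10,3.9,,2,10.0,0.39
month_to_month,RP83,menstrual_plasma,2,3,10,3.5,0.8,3,10.0,0.35
dose_response,RP54,menstrual_plasma,2,,1,3.6,2.1,3,1.0,0.036
dose_response,RP54,menstrual_plasma,2,,10,2.0,1.5,3,10.0,0.20
dose_response,RP54,menstrual_plasma,2,,25,1.2,0.2,3,25.0,0.30
dose_response,RP83,menstrual_plasma,2,,1,10.3,3.8,3,1.0,0.103
dose_response,RP83,menstrual_plasma,2,,10,3.3,0.7,8,10.0,0.33
dose_response,RP83,menstrual_plasma,2,,25,3.2,0.2,3,25.0,0.80
donor_pool,POOL4,menstrual_plasma,2,,10,12.2,1.5,3,10.0,1.22
systemic,SYSTEMIC_POOL,systemic_plasma,,,1,21.4,10.9,3,1.0,0.214
systemic,SYSTEMIC_POOL,systemic_plasma,,,10,6.3,0.5,3,10.0,0.63
systemic,SYSTEMIC_POOL,systemic_plasma,,,25,7.5,0.8,3,25.0,1.875
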