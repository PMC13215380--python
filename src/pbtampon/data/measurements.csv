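purpose,donor_id,cycle_day,cycle_month,matrix,spike_dose_ng_ml,incubation_min,conc_ng_ml,sd_ng_ml,n_replicates,adjusted
day_to_day,RP54,1,,whole_fluid,0,,3.30,0.05,3,False
day_to_day,RP54,1,,plasma,0,,0.24,0.19,3,True
day_to_day,RP54,1,,rbc,0,,2.66,0.22,3,True
day_to_day,RP54,2,,whole_fluid,0,,3.01,0.08,3,False
day_to_day,RP54,2,,plasma,0,,0.33,0.23,3,True
day_to_day,RP54,2,,rbc,0,,2.64,0.04,3,True
day_to_day,RP54,3,,whole_fluid,0,,2.43,,1,False
day_to_day,RP54,3,,plasma,0,,0.55,,1,True
day_to_day,RP54,3,,rbc,0,,1.18,,1,True
day_to_day,RP54,4,,whole_fluid,0,,3.47,,2,False
day_to_day,RP54,4,,plasma,0,,0.13,,2,True
day_to_day,RP54,4,,rbc,0,,1.71,,2,True
month_to_month,RP54,2,1,whole_fluid,0,,3.44,,2,False
month_to_month,RP54,2,1,plasma,0,,0.07,,2,True
month_to_month,RP54,2,1,rbc,0,,2.83,,2,True
month_to_month,RP54,2,2,whole_fluid,0,,3.01,0.08,3,False
month_to_month,RP54,2,2,plasma,0,,0.33,0.23,3,True
month_to_month,RP54,2,2,rbc,0,,2.64,0.04,3,True
month_to_month,RP54,2,3,whole_fluid,0,,2.74,0.09,3,False
month_to_month,RP54,2,3,plasma,0,,0.10,0.02,3,True
month_to_month,RP54,2,3,rbc,0,,1.52,,2,True
month_to_month,RP83,2,1,whole_fluid,0,,2.57,,2,False
month_to_month,RP83,2,1,plasma,0,,0.16,,2,True
month_to_month,RP83,2,1,rbc,0,,2.16,,2,True
month_to_month,RP83,2,2,whole_fluid,0,,2.29,0.23,3,False
month_to_month,RP83,2,2,plasma,0,,0.74,0.10,3,True
month_to_month,RP83,2,2,rbc,0,,0.99,0.20,3,True
month_to_month,RP83,2,3,whole_fluid,0,,2.66,0.05,3,False
month_to_month,RP83,2,3,plasma,0,,0.79,0.09,3,True
month_to_month,RP83,2,3,rbc,0,,1.85,0.06,3,True
donor_to_donor,RP54,2,,whole_fluid,0,,3.01,0.3,8,False
donor_to_donor,RP54,2,,plasma,0,,0.18,0.18,8,True
donor_to_donor,RP54,2,,rbc,0,,2.37,0.59,7,True
donor_to_donor,RP83,2,,whole_fluid,0,,2.50,0.22,8,False
donor_to_donor,RP83,2,,plasma,0,,0.61,0.29,8,True
donor_to_donor,RP83,2,,rbc,0,,1.61,0.54,8,True
donor_to_donor,RP115,2,,whole_fluid,0,,1.96,,2,False
donor_to_donor,RN1,2,,whole_fluid,0,,4.63,0.18,3,False
donor_to_donor,RN1,2,,plasma,0,,0.23,0.01,3,True
donor_to_donor,RN1,2,,rbc,0,,1.29,,2,True
donor_to_donor,RN2,2,,whole_fluid,0,,2.28,0.14,3,False
donor_to_donor,RN2,2,,plasma,0,,0.11,0.01,3,True
donor_to_donor,RN2,2,,rbc,0,,1.91,0.03,3,True
donor_to_donor,RN3,2,,whole_fluid,0,,4.08,,2,False
donor_to_donor,RN4,2,,whole_fluid,0,,1.94,,2,False
donor_to_donor,RN4,2,,plasma,0,,0.37,0.02,3,True
donor_to_donor,RN4,2,,rbc,0,,1.42,,2,True
donor_to_donor,RN5,2,,whole_fluid,0,,0.98,0.47,3,False
donor_to_donor,RN5,2,,plasma,0,,0.29,0.11,3,True
donor_to_donor,RN5,2,,rbc,0,,0.68,0.17,3,True
donor_to_donor,RN6,2,,whole_fluid,0,,2.28,0.52,3,False
donor_to_donor,RN6,2,,plasma,0,,0.92,0.03,3,True
donor_to_donor,RN6,2,,rbc,0,,0.69,0.13,3,True
donor_to_donor,RN8,2,,whole_fluid,0,,4.27,0.11,3,False
donor_to_donor,RN8,2,,plasma,0,,0.45,,2,True
donor_to_donor,RN8,2,,rbc,0,,2.47,,2,True
donor_to_donor,RN9,2,,whole_fluid,0,,4.81,,1,False
donor_to_donor,RN9,2,,plasma,0,,0.96,,1,True
donor_to_donor,RN9,2,,rbc,0,,1.44,,1,True
time_course,RP54,2,,whole_fluid,10,10,11.30,1.33,6,False
time_course,RP54,2,,plasma,10,10,1.24,0.31,6,True
time_course,RP54,2,,rbc,10,10,7.33,0.74,6,True
time_course,RP54,2,,whole_fluid,10,60,13.44,3.28,9,False
time_course,RP54,2,,plasma,10,60,0.38,0.23,9,True
time_course,RP54,2,,rbc,10,60,11.03,2.73,8,True
time_course,RP54,2,,whole_fluid,10,240,12.71,0.12,3,False
time_course,RP54,2,,plasma,10,240,0.19,0.01,3,True
time_course,RP54,2,,rbc,10,240,9.55,1.08,3,True
time_course,RP83,2,,whole_fluid,10,10,10.90,4.63,8,False
time_course,RP83,2,,plasma,10,10,6.50,3.96,8,True
time_course,RP83,2,,rbc,10,10,4.04,1.71,8,True
time_course,RP83,2,,whole_fluid,10,60,11.16,4.76,8,False
time_course,RP83,2,,plasma,10,60,5.69,3.54,8,True
time_course,RP83,2,,rbc,10,60,4.93,2.18,8,True
time_course,RP83,2,,whole_fluid,10,240,13.52,0.03,3,False
time_course,RP83,2,,plasma,10,240,4.38,0.03,3,True
time_course,RP83,2,,rbc,10,240,7.66,0.70,3,True
dose_response,RP54,2,,whole_fluid,0,60,3.01,0.3,8,False
dose_response,RP54,2,,plasma,0,60,0.18,0.18,8,True
dose_response,RP54,2,,rbc,0,60,2.37,0.59,7,True
dose_response,RP54,2,,whole_fluid,1,60,4.71,0.54,3,False
dose_response,RP54,2,,plasma,1,60,0.36,0.1,3,True
dose_response,RP54,2,,rbc,1,60,3.55,0.16,3,True
dose_response,RP54,2,,whole_fluid,10,60,13.44,3.28,9,False
dose_response,RP54,2,,plasma,10,60,0.38,0.23,9,True
dose_response,RP54,2,,rbc,10,60,11.03,2.73,8,True
dose_response,RP54,2,,whole_fluid,25,60,27.73,3.64,5,False
dose_response,RP54,2,,plasma,25,60,0.73,0.54,6,True
dose_response,RP54,2,,rbc,25,60,17.01,2.62,5,True
dose_response,RP83,2,,whole_fluid,0,60,2.5,0.22,8,False
dose_response,RP83,2,,plasma,0,60,0.61,0.29,8,True
dose_response,RP83,2,,rbc,0,60,1.61,0.54,8,True
dose_response,RP83,2,,whole_fluid,1,60,3.48,0.64,8,False
dose_response,RP83,2,,plasma,1,60,1.13,0.47,8,True
dose_response,RP83,2,,rbc,1,60,1.87,0.39,8,True
dose_response,RP83,2,,whole_fluid,10,60,11.16,4.76,8,False
dose_response,RP83,2,,plasma,10,60,5.69,3.54,8,True
dose_response,RP83,2,,rbc,10,60,4.93,2.18,8,True
dose_response,RP83,2,,whole_fluid,25,60,29.2,8.08,8,False
dose_response,RP83,2,,plasma,25,60,13.52,9.51,8,True
dose_response,RP83,2,,rbc,25,60,12.79,6.07,8,True
dose_response,RN1,2,,whole_fluid,10,60,15.17,0.12,3,False
dose_response,RN1,2,,plasma,10,60,6.41,0.02,3,True
dose_response,RN1,2,,rbc,10,60,6.36,0.002,3,True
dose_response,RN2,2,,whole_fluid,10,60,13.81,0.10,3,False
dose_response,RN2,2,,plasma,10,60,4.80,0.01,3,True
dose_response,RN2,2,,rbc,10,60,6.26,0.02,3,True
dose_response,RN4,2,,whole_fluid,10,60,14.40,0.44,3,False
dose_response,RN4,2,,plasma,10,60,5.02,0.04,3,True
dose_response,RN4,2,,rbc,10,60,5.50,0.16,3,True
dose_response,RN5,2,,whole_fluid,10,60,10.21,0.16,3,False
dose_response,RN5,2,,plasma,10,60,4.93,0.50,3,True
dose_response,RN5,2,,rbc,10,60,3.62,0.98,3,True
dose_response,RN6,2,,whole_fluid,10,60,11.90,0.03,3,False
dose_response,RN6,2,,plasma,10,60,7.49,0.03,3,True
dose_response,RN6,2,,rbc,10,60,4.12,0.28,3,True
dose_response,RN8,2,,whole_fluid,10,60,12.41,,2,False
dose_response,RN8,2,,plasma,10,60,13.25,,2,True
dose_response,RN8,2,,rbc,10,60,6.41,,2,True
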