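patient_id,age_decade,sex,axial_length_mm,mean_k_d,acd_mm,iol_model,implanted_power_d,postop_sphere_d,theoretical_power_d,diagnosis,va_preop_uc,va_preop_cc,va_postop_cc
B01,70s,M,23.31,44.61,2.91,,20.5,+4,22.12,,,,
B02,70s,M,24.03,42.70,3.38,,21,+5,22.63,,,,
B03,60s,M,23.73,43.72,3.22,,21,-0.5,22.02,,,,
B04,50s,M,24.89,43.2,3.51,,15,+2,18.998,,,,
B05,50s,F,21.77,45.52,2.31,,25,+3,26.33,,,,
B06,60s,F,22.29,47.44,2.65,,21.5,+0.5,22.02,,,,
B07,50s,M,23.15,42.32,3.76,,22,+3,26.5,,,,
B08,50s,F,23.53,42.59,2.85,,22.5,+3.75,24.32,,,,
B09,70s,F,23.56,43.86,3.18,,20,0,22.6,,,,
B10,50s,M,23,43.02,3.06,,23,+4.5,25.8,,,,
B11,40s,M,26.53,42.2,3.45,,13,+1.75,15.11,,,,
B12,60s,M,22.8,43.47,2.81,,24,-0.5,25.95,,,,
B13,60s,M,24.42,42.24,3.22,,21,+2.5,21.91,,,,
B14,40s,F,22.29,45.74,3.15,,19.5,+1.25,24.68,,,,
B15,60s,M,22.63,43.64,2.31,,22.5,0,25.43,,,,
B16,50s,M,25.03,43.09,3.27,,23,+1.75,18.32,,,,
B17,50s,M,23.43,43.37,2.93,,19,+3.5,23.28,,,,
B18,70s,M,23.67,43.58,2.87,,22,-1,23.98,,,,
B19,50s,M,23.16,42.91,2.76,,22,+1,26.96,,,,
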