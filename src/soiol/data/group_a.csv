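patient_id,age_decade,sex,axial_length_mm,mean_k_d,acd_mm,iol_model,implanted_power_d,postop_sphere_d,theoretical_power_d,diagnosis,va_preop_uc,va_preop_cc,va_postop_cc
A01,50s,M,23.91,40.89,2.74,,26,-7.0,25.23,PCV,1.40,0.92,0.7
A02,70s,F,21.83,46.46,3.01,,31,-6.50,26.06,RRD,1.50,1,0.82
A03,70s,F,23.98,43.23,3.24,,28,-6.25,21.7,PCV,1.40,1.22,0.92
A04,70s,M,24.7,41.6,2.95,,17,-1.50,21.66,RRD,1.40,1.4,0.6
A05,40s,M,22.61,44.35,3.34,,18,+8.0,25.99,ARN,2.00,2,0.82
A06,70s,F,21.01,45.83,2.68,,27.5,+3.0,30.38,RRD,1.22,0.82,0.82
A07,20s,F,22.35,42.98,3.04,,26,+2.50,28.70,ARN,1.80,1,0.82
A08,50s,F,20.37,46.31,3.27,,23.5,+4,26.43,PDR,1.60,1.1,0.9
A09,60s,F,22.84,42.51,2.38,,25,-0.5,26.19,RRD,1.80,1,0.8
A10,50s,M,23.78,44.86,2.54,,20,+1.0,19.68,PDR,2.00,1.8,1.4
A11,60s,M,23.92,42.85,3.27,,20.5,+3,22.47,PCV,1.20,0.8,0.5
A12,80s,M,21.92,44.07,3.13,,23,+4.5,28.54,PCV,1.90,1.6,1.0
A13,60s,M,23.4,44.95,2.69,,21,+1.5,21.45,PDR,1.90,1.6,1.0
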