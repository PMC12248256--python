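# Per-participant PM2.5 inhaled dose reference from the 20-participant pilot
# walking campaign: personalized minute ventilation (median/IQR over static
# points), sex-tabulated ventilation, personal and fixed-station PM2.5
# concentrations, and the inhaled dose by the wearable method (NEW) and the
# Standard Method (STD, 35 min of static exposure).
participant,vm_new_median_lpm,vm_new_iqr_lpm,vm_std_lpm,c_new_median_ugm3,c_new_iqr_ugm3,c_std_ugm3,id_new_ug,id_std_ug
P01,20.24,7.96,13.26,36.52,5.05,17,24.93,7.89
P02,13.64,6.64,15.14,9.84,9.88,19,5.59,10.07
P03,20.35,6.1,15.14,20.77,5.73,19,15.18,10.07
P04,14.43,4.09,13.26,20.87,4.36,28,10.41,12.99
P05,24.75,13.23,15.14,31.07,6.27,28,31.41,14.84
P06,15.71,9.14,13.26,19.35,7.4,27,12.33,12.53
P07,23.32,14.97,15.14,22.27,6.72,27,23.81,14.31
P08,20.05,12.86,15.14,1.24,0.96,7,1.07,3.71
P09,21.31,10.99,15.14,37.04,8.22,29,26.81,15.37
P10,14.77,7.14,15.14,44.91,7.24,29,24.32,15.37
P11,18.82,7.84,15.14,12.51,4.36,30,9.34,15.90
P12,18.19,6.71,13.26,26.73,8.9,30,16.00,13.92
P13,22.73,5.71,15.14,20.14,7.65,28,14.83,14.84
P14,30.9,12.45,15.14,14.06,10.2,28,16.11,14.84
P15,8.72,3.73,13.26,9.7,4.05,20,3.06,9.28
P16,16.3,8.44,15.14,4.6,1.6,21,3.11,11.13
P17,15.06,7.12,13.26,11.77,4.29,21,6.32,9.75
P18,18.2,5.27,15.14,46.24,6.84,40,26.73,21.20
P19,26.11,11.68,15.14,37.06,6.48,36,31.92,19.08
P20,16.9,5.61,15.14,39.64,9.05,36,22.11,19.08
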