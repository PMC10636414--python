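study_id,diagnosis,region,design,instrument,n_case,mean_case,sd_case,n_control,mean_control,sd_control,age_case,age_control,male_fraction,apd_recent,nos_score
Canan,depression,Turkey,prospective-cohort,DSM-4,84,9.50,1.80,575,8.90,1.40,40.6,43.8,NA,NA,NA
Cai,depression,China,case-control,DSM-4,103,9.39,0.60,106,9.06,0.85,46.6,46.6,NA,NA,NA
Ataoglu,depression,Turkey,case-control,DSM-4,15,10.92,0.75,17,10.01,0.75,37.1,35.6,NA,NA,NA
Wang,depression,China,case-control,ICD-10,61,9.96,0.93,30,9.83,0.93,42.0,37.1,NA,NA,NA
Ozturk,depression,Turkey,case-control,DSM-4,49,9.13,2.13,48,7.19,1.84,40.9,36.9,NA,NA,NA
Gunduz,depression,Turkey,case-control,DSM-4,75,8.12,1.70,57,7.26,1.28,31.7,32.4,NA,NA,NA
Almis,anxiety,Turkey,case-control,DSM-5,60,8.15,1.41,60,7.50,1.24,39.8,34.9,NA,NA,NA
Bondade,anxiety,India,case-control,DSM-5,76,9.84,1.32,49,8.77,0.44,35.1,34.7,NA,NA,NA
Mukta,anxiety,Bangladesh,cross-sectional,DSM-5,72,10.68,0.68,72,7.51,0.40,NA,NA,NA,NA,NA
Kokacya,anxiety,Turkey,case-control,DSM-4,61,10.12,0.32,63,8.27,0.91,23.5,26.6,NA,NA,NA
GogcegozGul,anxiety,Turkey,case-control,DSM-4,37,8.80,0.90,45,9.20,0.80,34.1,35.8,NA,NA,NA
Asoglu-PD,anxiety,Turkey,case-control,DSM-5,30,8.19,1.13,25,6.85,0.67,37.0,36.0,NA,NA,NA
Ransing,anxiety,India,case-control,DSM-4,123,7.53,0.93,133,8.91,1.24,31.9,31.3,NA,NA,NA
Yalamanchili,anxiety,India,case-control,ICD-10,65,10.02,0.37,65,6.96,0.99,31.5,32.5,NA,NA,NA
Mert,bipolar,Turkey,case-control,DSM-4,132,9.43,1.03,135,9.11,0.83,40.2,40.1,NA,NA,NA
Inanli,bipolar,Turkey,case-control,DSM-4,341,10.42,0.86,114,10.10,0.80,36.3,36.0,NA,NA,NA
Kirlioglu,bipolar,Turkey,case-control,DSM-5,48,9.18,1.98,32,8.96,2.02,37.1,38.8,NA,NA,NA
Kara,bipolar,Turkey,case-control,DSM-4,68,8.57,1.42,60,7.92,1.41,34.7,32.5,NA,NA,NA
Semiz,schizophrenia,Turkey,case-control,DSM-4,25,8.95,0.84,30,8.10,0.90,41.3,41.3,NA,NA,NA
Asoglu-SCZ,schizophrenia,Turkey,case-control,DSM-5,56,7.17,1.17,30,6.90,0.69,34.0,33.0,NA,NA,NA
Aydin,schizophrenia,Turkey,case-control,DSM-4,100,10.34,0.93,37,9.97,0.97,37.7,35.0,NA,NA,NA
Yu,schizophrenia,China,cross-sectional,DSM-5,106,11.11,0.11,120,10.70,0.06,23.7,22.6,NA,NA,NA
Balcioglu,schizophrenia,Turkey,cross-sectional,ICD-10,618,9.31,1.88,445,8.90,1.98,39.7,31.2,NA,NA,NA
Ali,schizophrenia,Egypt,cross-sectional,DSM-5,45,9.64,0.84,45,9.03,1.14,32.4,33.0,NA,NA,NA
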