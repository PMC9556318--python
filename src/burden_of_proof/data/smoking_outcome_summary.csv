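outcome,exposure_measure,direction,is_binary,p85_exposure,ros,average_bprf,average_increased_risk_pct,stars_published,pub_bias,n_studies
Laryngeal cancer,pack_years,harmful,0,50.50,1.56,4.75,374.95,5,0,5
Aortic aneurysm,cigarettes_per_day,harmful,0,30.00,0.92,2.50,149.73,5,0,14
Peripheral artery disease,cigarettes_per_day,harmful,0,31.25,0.86,2.37,136.53,5,0,6
Lung cancer,pack_years,harmful,0,50.88,0.73,2.07,106.66,5,1,78
Other pharynx cancer,pack_years,harmful,0,63.75,0.65,1.92,92.26,5,0,8
COPD,pack_years,harmful,0,49.75,0.54,1.72,72.11,4,1,13
Lower respiratory infection,cigarettes_per_day,harmful,0,31.25,0.43,1.54,54.45,4,0,7
Pancreatic cancer,pack_years,harmful,0,51.25,0.42,1.52,51.66,4,0,19
Bladder cancer,pack_years,harmful,0,50.65,0.34,1.40,40.18,3,1,30
Tuberculosis,cigarettes_per_day,harmful,0,26.56,0.27,1.31,31.04,3,0,19
Esophageal cancer,pack_years,harmful,0,50.00,0.26,1.29,29.36,3,1,14
Cervical cancer,pack_years,harmful,0,25.50,0.21,1.24,23.53,3,0,4
Multiple sclerosis,cigarettes_per_day,harmful,0,20.00,0.21,1.23,23.36,3,0,6
Rheumatoid arthritis,cigarettes_per_day,harmful,0,26.25,0.21,1.23,23.32,3,1,6
Lower back pain,cigarettes_per_day,harmful,0,26.25,0.20,1.22,21.84,3,0,6
Ischemic heart disease,cigarettes_per_day,harmful,0,31.25,0.19,1.20,20.39,3,1,60
Peptic ulcer,cigarettes_per_day,harmful,0,21.94,0.18,1.20,19.84,3,0,7
Macular degeneration,cigarettes_per_day,harmful,0,27.50,0.18,1.19,19.44,3,0,2
Parkinson's disease,cigarettes_per_day,protective,0,26.25,0.16,0.85,-14.88,3,1,14
Stomach cancer,pack_years,harmful,0,51.13,0.16,1.17,17.39,3,1,13
Stroke,cigarettes_per_day,harmful,0,29.50,0.16,1.17,16.89,3,0,67
Type 2 diabetes,cigarettes_per_day,harmful,0,26.25,0.15,1.16,15.76,3,1,28
Cataracts,cigarettes_per_day,harmful,0,25.00,0.14,1.15,15.47,3,0,10
Nasopharyngeal cancer,pack_years,harmful,0,50.00,0.13,1.14,14.29,2,1,12
Alzheimer's and other dementia,cigarettes_per_day,harmful,0,30.00,0.09,1.10,9.70,2,1,8
Gallbladder diseases,cigarettes_per_day,harmful,0,27.93,0.06,1.06,6.34,2,0,4
Atrial fibrillation and flutter,cigarettes_per_day,harmful,0,25.00,0.06,1.06,5.67,2,0,5
Lip and oral cavity cancer,pack_years,harmful,0,49.68,0.05,1.05,4.81,2,0,10
Breast cancer,pack_years,harmful,0,34.10,0.04,1.04,4.46,2,0,23
Colon and rectum cancer,pack_years,harmful,0,50.00,-0.01,0.99,,1,0,16
Kidney cancer,pack_years,harmful,0,45.86,-0.01,0.99,,1,1,18
Leukemia,pack_years,harmful,0,37.50,-0.04,0.96,,1,0,7
Fracture,binary,harmful,1,1.00,-0.05,0.95,,1,0,59
Prostate cancer,cigarettes_per_day,harmful,0,29.73,-0.06,0.94,,1,1,22
Liver cancer,pack_years,harmful,0,62.50,-0.32,0.72,,1,0,11
Asthma,cigarettes_per_day,harmful,0,26.25,-0.64,0.53,,1,0,7
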