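borehole,water_type,group,sample_date,doc_mgL,doc_sd,tdn_mgL,tdn_sd,extracted_doc_mgL
LMO,Baltic Sea,baltic,2019-04,3.79,0.07,0.24,0.01,2.39
Aspo,Baltic Sea,baltic,2019-04,7.05,0.06,0.43,0.01,4.79
SA1229A_1,BrMarine1,groundwater,2018-11,5.81,0.21,5.62,0.16,4.30
SA1229A_1,BrMarine1,groundwater,2019-04,5.84,0.07,5.52,0.10,4.38
KA2051A01_5,BrMarine1,groundwater,2019-03,6.20,0.09,0.33,0.01,4.90
KA2511A_5,BrMarine1,groundwater,2019-03,4.47,0.04,0.69,0.01,3.40
KA3105A_3,BrMarine2,groundwater,2018-11,4.58,0.13,0.38,0.00,3.57
KA3105A_3,BrMarine2,groundwater,2019-03,4.44,0.05,0.38,0.02,3.64
KA3600F_2,BrMarine2,groundwater,2018-11,3.97,0.03,0.45,0.02,3.14
KA3600F_2,BrMarine2,groundwater,2019-03,3.85,0.03,0.44,0.03,3.00
KA2865A01_1,Transition,groundwater,2019-03,2.94,0.02,0.29,0.02,2.29
KA3385A_1,Transition,groundwater,2019-03,1.17,0.02,0.13,0.01,1.02
KA3510A_2,Transition,groundwater,2019-03,1.41,0.04,0.10,0.01,1.14
SA2600A_1,Saline,groundwater,2018-11,0.90,0.05,0.11,0.02,0.78
SA2600A_1,Saline,groundwater,2019-03,0.95,0.04,0.10,0.01,0.78
HA2780A_1,Saline,groundwater,2019-03,0.85,0.04,0.08,0.01,0.71
SA1730A_1,Saline,groundwater,2018-11,0.78,0.01,0.09,0.01,0.69
SA1730A_1,Saline,groundwater,2019-03,0.98,0.01,0.09,0.01,0.80
KA1755A_3,Saline,groundwater,2019-03,0.76,0.04,0.08,0.02,0.60
KA2862A_1,Saline,groundwater,2019-03,0.92,0.04,0.08,0.01,0.75
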