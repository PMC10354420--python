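study_id,region,n_trt,n_ctl,mean_age_trt,mean_age_ctl,n_male,n_female,dis_dur_trt,dis_dur_ctl,bailing_dose,trt_duration_value,trt_duration_unit
B59,Zhejiang,42,42,47.02,46.88,58,26,1.31,1.26,0.8 g*3 times/d,3,months
B44,Henan,46,46,58.79,59.13,51,41,0.33,0.35,2 g*3 times/d,12,weeks
B66,Hubei,47,47,60.39,61.03,55,39,8.94,9.12,3 tablets*3 times/d,12,weeks
B68,Shandong,50,50,62.48,61.22,54,46,1.39,1.43,1 g*3 times/d,2,months
B18,Hebei,70,70,56.3,58.6,85,55,5.9,6.2,1 g*3 times/d,3,months
B26,Hubei,58,58,55.2,55.7,61,55,5.48,5.7,1 g*3 times/d,12,weeks
B41,Hebei,60,60,49.8,50.3,68,52,7.3,7.7,1 g*3 times/d,3,months
B25,Guangdong,80,80,56.8,56.6,92,68,1.7,1.8,2 tablets*3 times/d,2,months
B55,Chongqing,69,69,61.7,61.2,75,63,8.5,8.3,3 tablets*3 times/d,4,months
B49,Zhejiang,40,40,61.6,62.1,45,35,4.8,5.1,1 g*3 times/d,4,weeks
B47,Henan,41,41,67.12,66.48,58,24,10.98,11.08,8 tablets*3 times/d,3,months
B13,Zhejiang,42,42,51.91,52.29,54,30,9.27,9.11,4 tablets*3 times/d,2,weeks
B32,Henan,45,45,59.3,56.7,53,37,15.8,14.9,1 g*3 times/d,12,weeks
B33,Fujian,31,31,53.6,54.8,27,35,3.58,4.56,1 g*3 times/d,3,months
B19,Shaanxi,80,80,48.7,48.7,87,73,9.3,9.3,0.4 g*3 times/d,3,months
B23,Zhejiang,50,50,55.3,54.1,54,46,11.9,11.5,8 tablets*3 times/d,12,weeks
B11,Liaoning,31,31,53.28,55.61,34,28,,,1-2 g*3 times/d,4,weeks
B10,Henan,46,46,48.21,47.42,45,47,5.14,5.84,0.5 g*3 times/d,8,weeks
B65,Hunan,57,55,59.60,58.53,65,47,3.56,3.42,1 g*3 times/d,16,weeks
B53,Henan,53,53,53.02,53.52,48,58,6.89,6.23,4 tablets*3 times/d,2,weeks
B45,Guangdong,42,42,54.38,54.38,48,36,8.47,8.47,4 tablets*3 times/d,2,weeks
B46,Sichuan,35,35,57.14,56.37,42,28,,,1 g*3 times/d,8,weeks
B63,Henan,31,31,56.71,57.48,31,31,,,1 g*3 times/d,4,months
B39,Peking,75,75,54.2,53.2,87,54,7.1,7.2,6 tablets*3 times/d,3,months
B54,Guangxi,41,41,62.8,63.1,42,40,,,3 times/d,12,weeks
B57,Shandong,72,70,59.04,60.34,89,53,8.50,8.80,2 g*3 times/d,3,months
B56,Hubei,45,45,72.3,71.4,53,37,,,1 g*3 times/d,12,weeks
B27,Liaoning,40,40,60.0,60.0,40,40,,,1 g*3 times/d,12,weeks
B37,Henan,85,85,38.80,38.20,130,40,,,2 g*3 times/d,8,weeks
B51,Shaanxi,50,50,68.8,69.7,61,39,2.7,2.8,5 tablets*3 times/d,6,months
B50,Liaoning,48,48,61.8,64.7,46,50,8.6,8.3,2 g*3 times/d,3,months
B4,Henan,44,44,52.32,54.01,47,41,5.72,6.32,0.8 g*3 times/d,4,weeks
B7,Qinghai,43,43,74.07,73.07,45,41,10.06,9.53,5 tablets*3 times/d,8,weeks
B2,Guangxi,35,35,62.3,63.4,36,34,,,1 g*3 times/d,12,weeks
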