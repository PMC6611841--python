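patient_id,n_windows,sensor_distance_cm,heart_rate_bpm,heart_rate_sd,resp_rate_bpm,resp_rate_sd,cardiac_grad_mmHg_per_m,cardiac_grad_sd,resp_grad_mmHg_per_m,resp_grad_sd,grad_amplitude_ratio
1,21,6.8,78,9,17,2,1.59,0.47,0.72,0.23,2.22
2,56,5.5,51,9,15,4,1.52,0.85,0.46,0.12,3.31
3,53,7.0,67,2,15,3,1.83,0.74,0.36,0.09,5.11
4,105,5.3,59,4,13,3,1.11,0.47,0.58,0.27,1.91
5,89,3.2,59,4,14,3,3.23,1.12,0.88,0.29,3.67
6,55,7.0,74,7,17,3,0.86,0.23,0.41,0.13,2.13
7,60,7.9,53,7,17,4,0.93,0.52,0.30,0.12,3.06
8,27,5.7,54,3,15,3,0.99,0.61,0.51,0.23,1.94
9,36,5.3,64,4,16,4,1.09,0.43,0.48,0.17,2.26
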