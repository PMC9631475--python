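scenario,ees_rv,ea_rv,ees_over_ea,sw_rv,mvo2_rv,pe_rv,pva_rv,eff_rv,psa,psa_max,psa_min,ppa,ppa_max,ppa_min,dp_aov,qao,qlvad,v_back,net_flow,rf
coupled_severe_baseline,0.364,0.477,0.762,851,0.0447,726,1577,0.127,92,97,88,24,28,19,57,-3.33,5.42,-59,2.10,0.613
coupled_severe_speed_augmentation,0.360,0.408,0.884,860,0.0440,684,1544,0.130,99,101,96,22,28,18,67,-4.07,7.05,-68,2.97,0.578
coupled_severe_bp_control,0.356,0.333,1.069,827,0.0413,589,1416,0.133,73,78,69,20,26,16,43,-2.47,6.26,-50,3.80,0.394
coupled_mild_moderate_baseline,0.364,0.379,0.959,862,0.0435,659,1520,0.132,92,94,90,22,27,17,58,-0.87,5.35,-15,4.47,0.163
coupled_mild_moderate_speed_augmentation,0.351,0.273,1.285,805,0.0401,555,1360,0.134,88,89,87,19,25,14,63,-0.99,7.20,-16,6.21,0.137
coupled_mild_moderate_bp_control,0.354,0.271,1.310,816,0.0398,532,1348,0.136,72,75,70,18,25,14,44,-0.42,6.22,-12,5.80,0.067
uncoupled_severe_baseline,0.340,1.192,0.285,754,0.0602,1564,2318,0.083,83,88,79,21,41,13,57,-3.78,5.56,-63,1.78,0.679
uncoupled_severe_speed_augmentation,0.331,0.979,0.338,842,0.0595,1445,2287,0.094,89,92,87,21,39,13,72,-4.34,6.92,-72,2.59,0.626
uncoupled_severe_bp_control,0.339,0.918,0.370,822,0.0578,1384,2206,0.095,79,82,76,21,39,13,53,-3.62,5.80,-60,2.19,0.624
uncoupled_severe_pulmonary_vasodilation,0.364,0.477,0.762,851,0.0447,726,1577,0.127,92,97,88,24,28,19,57,-3.33,5.42,-59,2.10,0.613
uncoupled_severe_pulm_vasodilation_plus_bp,0.356,0.333,1.069,827,0.0413,589,1416,0.133,73,78,69,20,26,16,43,-2.47,6.26,-50,3.80,0.394
uncoupled_mild_moderate_baseline,0.327,0.857,0.381,891,0.0584,1345,2235,0.101,84,86,82,20,38,13,69,-1.05,5.05,-17,4.00,0.208
uncoupled_mild_moderate_speed_augmentation,0.315,0.585,0.540,994,0.0530,988,1982,0.125,82,82,82,19,34,12,75,-1.10,6.86,-18,5.77,0.160
uncoupled_mild_moderate_bp_control,0.326,0.597,0.547,977,0.0538,1038,2015,0.121,72,73,71,19,34,13,55,-0.93,5.80,-15,4.87,0.160
uncoupled_mild_moderate_pulmonary_vasodilation,0.364,0.379,0.959,862,0.0435,659,1520,0.132,92,94,90,22,27,17,58,-0.87,5.35,-15,4.47,0.163
uncoupled_mild_moderate_pulm_vasodilation_plus_bp,0.354,0.271,1.310,816,0.0398,532,1348,0.136,72,75,70,18,25,14,44,-0.42,6.22,-12,5.80,0.067
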