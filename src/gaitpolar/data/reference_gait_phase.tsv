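subject_id	group	phase_mean	phase_sd
subject_01	healthy	6.272	0.019
subject_02	healthy	6.265	0.016
subject_03	healthy	6.279	0.025
subject_04	healthy	6.275	0.022
subject_05	healthy	6.276	0.016
subject_06	healthy	6.275	0.016
subject_07	healthy	6.277	0.018
subject_08	healthy	6.278	0.019
subject_09	stroke	6.273	0.017
subject_10	stroke	6.255	0.016
subject_11	stroke	6.263	0.016
subject_12	stroke	6.255	0.015
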