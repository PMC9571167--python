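subject_id	group	arearatio_R	arearatio_L	ari	ang_tangent	ppd	pci
subject_01	healthy	49.9	50.1	0.2	0.03	5.86	7.93
subject_02	healthy	53.1	46.9	6.1	0.11	5.50	13.18
subject_03	healthy	48.8	51.2	2.5	0.02	9.09	6.95
subject_04	healthy	46.5	53.5	6.9	0.14	8.84	8.18
subject_05	healthy	52.1	47.9	4.2	0.00	8.89	11.23
subject_06	healthy	48.9	51.1	2.1	0.05	8.89	12.71
subject_07	healthy	50.2	49.8	0.3	0.08	8.44	6.71
subject_08	healthy	50.5	49.5	1.1	0.11	6.65	7.20
subject_09	stroke	60.9	39.1	21.8	0.21	18.97	12.97
subject_10	stroke	63.2	36.8	26.4	0.42	11.05	14.35
subject_11	stroke	56.1	43.9	12.2	0.24	25.89	13.85
subject_12	stroke	36.0	64.0	28.0	0.17	34.92	14.05
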