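family	andean_mbp	non_andean_mbp	location
TinfSat01-33	228.78	37.76	H: A+X*+Y
TinfSat02-79	174.83	149.63	H: A
TinfSat03-4	88.87	66.29	H: A+X*+Y
TinfSat04-1000	82.86	40.52	E: A+X
TinfSat05-4	27.56	14.15	H: A
TinfSat06-181	4.66	1.42	E: A+X
TinfSat07-10	2.53	0.15	E: A+X
TinfSat08-239	1.55	1.05	E: A+X
TinfSat09-113	1.36	3.35	E: A+X
TinfSat10-53	0.97	0.45	E: A+X
TinfSat11-85	0.58	0.45	E: A+X
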