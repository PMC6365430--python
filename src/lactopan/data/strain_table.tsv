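strain	genotype	phenotype	origin	genome_size_mb	protein_count	plasmid_kb	status
KW10	cremoris	lactis	Kaanga Wai	2.36	2285	0	draft
KW2	cremoris	lactis	Kaanga Wai	2.43	2327	0	complete
V4	cremoris	lactis	Raw sheep milk	2.55	2591	67.78	draft
N41	cremoris	lactis	Soil and grass	2.61	2655	154.58	draft
NCDO763	cremoris	lactis	Dairy starter	2.48	2553	100.62	draft
MG1363	cremoris	lactis	Dairy starter	2.53	2647	0	complete
SK110	cremoris	cremoris	Dairy starter	2.46	2597	149	draft
AM2	cremoris	cremoris	Dairy starter	2.47	2617	59.04	draft
SK11	cremoris	cremoris	Dairy starter	2.44	2780	150	complete
A76	cremoris	cremoris	Cheese factory	2.45	2786	120	complete
UC509_9	cremoris	cremoris	Dairy starter	2.25	2600	210	complete
B40	cremoris	cremoris	Dairy starter	2.48	2641	153.47	draft
FG2	cremoris	cremoris	Dairy starter	2.57	2729	138.97	draft
HP	cremoris	cremoris	Dairy starter	2.38	2556	126.1	draft
LMG6897	cremoris	cremoris	Cheese starter	2.36	2527	100.11	draft
LMG8526	lactis	lactis	Chinese radish seeds	2.48	2459	75.36	draft
KF282	lactis	lactis	Mustard and cress	2.65	2610	16.6	draft
LMG8520	other	lactis	Leaf hopper	2.43	2683	126.93	draft
IO_1	lactis	lactis	Drain water	2.42	2333	0	complete
K231	lactis	lactis	White Kimchi	2.34	2311	17.17	draft
Li-1	lactis	lactis	Grass	2.48	2450	90.16	draft
KF24	lactis	lactis	Alfalfa sprouts	2.61	2670	51.05	draft
LMG9447	lactis	lactis	Frozen peas	2.69	2792	114.17	draft
ATCC19435	lactis	lactis	Dairy starter	2.54	2581	64.11	draft
E34	lactis	lactis	Silage	2.38	2310	0.8	draft
K337	lactis	lactis	White Kimchi	2.42	2407	0	draft
KF201	lactis	lactis	Sliced mixed vegetables	2.38	2344	0	draft
M20	lactis	diacetylactis	Soil	2.67	2681	41.86	draft
N42	lactis	lactis	Soil and grass	2.73	2769	165.55	draft
DRA4	lactis	diacetylactis	Dairy starter	2.44	2503	0	draft
IL1403	lactis	lactis	Dairy starter	2.37	2448	0	complete
CV56	lactis	lactis	Human vagina	2.4	2563	120	complete
ML8	lactis	lactis	Dairy starter	2.5	2576	142.37	draft
UC317	lactis	lactis	Dairy starter	2.49	2565	0	draft
LMG14418	lactis	lactis	Bovine milk	2.41	2445	19.01	draft
KLDS 4.0325	lactis	lactis	Koumiss	2.59	2656	170	complete
KF147	lactis	lactis	Mung bean sprouts	2.6	2638	40	complete
KF7	lactis	lactis	Alfalfa sprouts	2.37	2357	20.96	draft
KF67	lactis	lactis	Grapefruit juice	2.68	2669	49.11	draft
KF196	lactis	lactis	Japanese Kaiware shoots	2.45	2387	26.24	draft
KF146	lactis	lactis	Alfalfa and radish sprouts	2.58	2546	59.05	draft
KF134	lactis	lactis	Alfalfa and radish sprouts	2.47	2418	1.1	draft
LMG9446	lactis	lactis	Frozen peas	2.49	2494	77.32	draft
P7266	other	unknown	Litter on pasture	2	1980	24.72	draft
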