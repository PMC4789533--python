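id	name	hemisphere	cluster
1	L_caudalmiddlefrontal	L	motor_premotor
2	R_caudalmiddlefrontal	R	motor_premotor
3	L_precentral	L	motor_premotor
4	R_precentral	R	motor_premotor
5	L_frontalpole	L	dlpfc
6	R_frontalpole	R	dlpfc
7	L_rostralmiddlefrontal	L	dlpfc
8	R_rostralmiddlefrontal	R	dlpfc
9	L_parstriangularis	L	dlpfc
10	R_parstriangularis	R	dlpfc
11	L_parsorbitalis	L	dlpfc
12	R_parsorbitalis	R	dlpfc
13	L_rostralanteriorcingulate	L	cma
14	R_rostralanteriorcingulate	R	cma
15	L_posteriorcingulate	L	cma
16	R_posteriorcingulate	R	cma
17	L_paracentral	L	sma
18	R_paracentral	R	sma
19	L_superiorfrontal	L	sma
20	R_superiorfrontal	R	sma
21	L_postcentral	L	parietal
22	R_postcentral	R	parietal
23	L_supramarginal	L	parietal
24	R_supramarginal	R	parietal
25	L_superiorparietal	L	parietal
26	R_superiorparietal	R	parietal
27	L_inferiorparietal	L	parietal
28	R_inferiorparietal	R	parietal
29	L_thalamusproper	L	subcortical
30	R_thalamusproper	R	subcortical
31	L_caudate	L	subcortical
32	R_caudate	R	subcortical
33	L_putamen	L	subcortical
34	R_putamen	R	subcortical
35	L_pallidum	L	subcortical
36	R_pallidum	R	subcortical
37	L_accumbensarea	L	subcortical
38	R_accumbensarea	R	subcortical
39	Brainstem	NA	brainstem
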