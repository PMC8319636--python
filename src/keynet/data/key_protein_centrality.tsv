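protein	degree	betweenness	uniprot_accession
IL10	24	300.549477	P22301
TLR4	24	253.174429	O00206
IL6	29	208.838661	P05231
AKT1	17	204.665414	P31749
CRP	15	190.958865	P02741
IL4	18	127.805378	P05112
CXCL8	22	118.536469	P10145
TNF	25	116.879025	P01375
ITGAM	17	94.1162934	P11215
CCL2	22	70.1571213	P13500
NOS3	11	62.2581681	P29474
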