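protein	P1	P2	P3	P4	P5	P6	P7	P8	P9	C1	C2	median_fd	n_above
Cancer antigen 125 (CA125)	7.2	8.9	18.2	27.7	16.5	5.2	33.1	40.2	17.8	0.5	0.3	17.8	9
Kallikrein 11 (KLK11)	9.3	0.4	11.8	5.4	1.6	30.4	4.9	41.8	5.6	1.9	1.7	5.6	7
Folate receptor 1 (FOLR1)	18.3	0.6	4.6	0.1	33.4	6.6	4.9	32.4	1.0	0.0	0.0	4.9	6
Kallikrein 5 (KLK5)	14.8	1.8	2.5	0.1	7.0	19.1	3.4	10.4	4.5	1.7	1.9	4.5	7
Renin	5.1	2.1	0.8	1.3	0.8	2.8	6.2	5.1	2.8	1.9	1.3	2.8	6
Activin Receptor Type 1 (ACVR1)	1.6	2.8	0.8	3.0	4.6	2.5	5.3	1.3	4.3	0.2	0.0	2.8	6
Nicotinamide phosphoribosyltransferase (NAMPT)	3.7	1.9	4.8	2.5	0.9	2.7	4.2	5.0	1.5	1.2	0.0	2.7	6
Signaling lymphocytic activation molecule (SLAM)	5.3	2.7	5.1	0.9	0.7	2.8	2.1	2.7	1.6	0.0	0.0	2.7	6
Kallikrein 7 (KLK7)	9.9	1.4	1.7	2.3	0.6	3.6	3.8	2.6	4.7	1.4	0.6	2.6	6
Cartilage oligomeric matrix protein (COMP)	3.9	2.6	2.3	1.3	1.1	2.5	3.4	2.1	1.7	0.9	1.0	2.3	6
Toll-like receptor 1 (TLR1)	12.0	2.0	1.4	1.2	0.7	2.3	2.2	4.3	4.6	1.8	0.9	2.2	6
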