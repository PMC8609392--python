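protein	P1	P2	P3	P4	P5	P6	P7	P8	P9	C1	C2	median_fd	n_above
Cancer antigen 125 (CA125)	4.1	4.8	6.9	42.0	10.5	5.4	18.8	30.2	14.1	0.9	1.0	10.5	9
Folate receptor 1 (FOLR1)	20.4	1.6	4.6	1.2	43.7	10.5	21.1	22.2	2.5	1.0	0.8	10.5	7
Keratin type I cytoskeletal 19 (KRT19)	12.8	2.4	10.2	0.9	17.2	12.9	8.4	16.5	3.4	0.6	0.6	10.2	8
Kallikrein-10 (KLK10)	8.4	2.5	11.5	1.0	3.4	8.7	19.4	16.0	0.9	1.0	0.6	8.4	7
Mesothelin (MSLN)	4.8	1.6	2.2	1.3	5.7	6.6	12.4	7.4	2.7	1.0	0.8	4.8	7
Poly [ADP-ribose] polymerase 1 (PARP-1)	14.9	1.3	1.6	2.5	15.9	1.3	4.6	13.0	4.9	1.2	1.3	4.6	6
Glycodelin (PAEP)	5.0	4.1	3.8	6.3	8.1	2.3	4.5	11.3	4.0	0.5	0.6	4.5	9
Kallikrein-11 (KLK11)	4.1	1.5	4.3	2.9	4.3	3.8	5.9	5.3	1.7	1.1	0.8	4.1	7
Kallikrein-6 (KLK6)	3.2	1.3	7.4	1.0	3.0	6.1	4.6	15.0	1.0	0.9	0.8	3.2	6
Interferon lambda-1 (IFNL1)	5.9	2.8	1.9	2.1	3.1	3.4	14.5	4.1	1.7	0.8	0.8	3.1	7
Basal cell adhesion molecule (BCAM)	6.5	1.3	2.1	1.4	2.9	4.3	4.4	5.5	1.1	0.9	1.0	2.9	6
Epithelial cell adhesion molecule (EPCAM)	1.3	2.5	3.0	2.1	2.3	5.3	1.5	8.0	3.2	1.0	0.9	2.5	7
Kallikrein-8 (KLK8)	3.2	1.2	3.3	1.4	2.4	3.5	2.0	3.5	1.3	1.0	0.8	2.4	6
Trophoblast antigen 2 (TROP2)	8.8	2.0	1.1	1.3	1.4	8.1	6.4	6.8	2.1	0.9	0.8	2.1	6
Human epididymis protein 4 (HE4)	3.2	1.4	1.6	2.1	2.6	2.1	3.8	2.0	2.4	1.1	0.8	2.1	6
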