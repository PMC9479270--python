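transcript_id	p_cia_vs_control	p_bzxd_vs_cia	fc_cia_vs_control	fc_bzxd_vs_cia	reg_cia_vs_control	reg_bzxd_vs_cia	chromosome	strand	relationship
ENSRNOT00000077623	0.0454	0.0000	4.07	104.02	Down	Up	chr1	-	Exon sense-overlapping
ENSRNOT00000084356	0.0452	0.0000	3.13	70.79	Down	Up	chr18	+	Intergenic
ENSRNOT00000090476	0.0402	0.0000	4.43	39.24	Down	Up	chr3	+	Intergenic
ENSRNOT00000079825	0.0471	0.0000	4.77	32.76	Down	Up	chr2	+	Intergenic
ENSRNOT00000088010	0.0391	0.0000	2.51	25.29	Down	Up	chr3	+	Intergenic
ENSRNOT00000092850	0.0156	0.0000	2.54	18.57	Down	Up	chr12	+	Intron sense-overlapping
uc.361−	0.0000	0.0009	4.89	111.56	Up	Down	chr6	-	Intergenic
ENSRNOT00000092834	0.0001	0.0016	5.51	79.60	Up	Down	chr8	-	Intergenic
ENSRNOT00000089244	0.0016	0.0013	3.81	59.99	Up	Down	chr11	-	Intergenic
ENSRNOT00000090140	0.0014	0.0010	3.86	40.06	Up	Down	chr6	+	Intergenic
ENSRNOT00000076778	0.0001	0.0013	9.05	39.34	Up	Down	chrX	+	Intergenic
ENSRNOT00000084631	0.0009	0.0011	4.49	23.51	Up	Down	chr10	+	Intergenic
XR_594820	0.0000	0.0001	3.57	22.94	Up	Down	chr15	-	Intergenic
XR_343493	0.0023	0.0001	4.11	17.93	Up	Down	chr1	-	Intergenic
uc.183−	0.0000	0.0018	16.59	14.56	Up	Down	chr10	+	Exon sense-overlapping
XR_589160	0.0027	0.0055	4.67	10.53	Up	Down	chr8	+	Intergenic
ENSRNOT00000080854	0.0031	0.0002	2.40	9.53	Up	Down	chr8	-	Intergenic
ENSRNOT00000083731	0.0066	0.0000	2.26	6.85	Up	Down	chr8	-	Intergenic
uc.229−	0.0005	0.0000	2.26	6.74	Up	Down	chr4	-	Intergenic
XR_590741	0.0002	0.0001	3.93	6.16	Up	Down	chr1	+	Intergenic
ENSRNOT00000089400	0.0016	0.0000	2.12	5.92	Up	Down	chr20	-	Intergenic
uc.301−	0.0017	0.0009	2.45	5.87	Up	Down	chr1	-	Intronic antisense
XR_342867	0.0116	0.0043	2.24	5.83	Up	Down	chr1	+	Intergenic
XR_592829	0.0004	0.0045	8.76	5.54	Up	Down	chr6	+	Intergenic
uc.279+	0.0042	0.0001	2.53	4.92	Up	Down	chr3	-	Intron sense-overlapping
XR_359049	0.0018	0.0001	2.42	4.32	Up	Down	chr13	+	Intergenic
XR_592983	0.0000	0.0000	2.41	4.23	Up	Down	chr6	-	Intronic antisense
uc.72+	0.0044	0.0002	2.17	3.70	Up	Down	chr3	+	Intronic antisense
XR_601424	0.0150	0.0075	2.60	3.69	Up	Down	chr6	+	Exon sense-overlapping
ENSRNOT00000080985	0.0034	0.0057	2.84	3.38	Up	Down	chr17	+	Intergenic
XR_345040	0.0237	0.0023	2.03	3.27	Up	Down	chr3	+	Intergenic
ENSRNOT00000077852	0.0040	0.0001	2.05	2.94	Up	Down	chr1	-	Intergenic
XR_341569	0.0022	0.0069	2.31	2.61	Up	Down	chr17	+	Intergenic
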