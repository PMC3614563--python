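position	gene	var_type	af_exome_OV	af_exome_OMN	af_exome_REC	af_sanger_OV	af_sanger_OMN	af_sanger_REC
chr10:106124579	CCDC147	snv	0.31	0.45	0.52	0.40	0.71	0.76
chr17:38173081	CSF3	snv	0.26	0.49	0.66	0.23	0.43	0.58
chr15:64496758	CSNK1G1	snv	0.31	0.50	0.48	0.46	0.57	0.57
chr17:11696980	DNAH9	snv	0.24	0.42	0.62	0.21	0.36	0.56
chr4:88533803	DSPP	snv	0.27	0.61	0.52	0.20	0.51	0.45
chr20:33874597	FAM83C	snv	0.16	0.44	0.40	0.17	0.30	0.38
chr6:5369392	FARS2	snv	0.20	0.36	0.35	0.16	0.35	0.36
chr14:25076412	GZMH	snv	0.17	0.40	0.37	0.15	0.28	0.33
chr10:126477647	METTL10	snv	0.14	0.57	0.60	0.19	0.58	0.40
chrX:153040228	PLXNB3	snv	0.17	0.21	0.19	0.29	0.33	0.37
chr12:3692299	PRMT8	snv	0.30	0.55	0.55	0.35	0.57	0.58
chr2:65316194	RAB1A	snv	0.18	0.37	0.39	0.23	0.62	0.54
chr7:122338859	RNF133	snv	0.17	0.36	0.34	0.15	0.32	0.40
chrX:30870990	TAB3	snv	0.09	0.37	0.39	0.15	0.33	0.36
chr1:234565362	TARBP1	snv	0.28	0.50	0.53	0.34	0.45	0.57
chr17:7579358	TP53	snv	0.21	0.47	0.68	0.02	0.44	0.47
chr7:158824649	VIPR2	snv	0.13	0.63	0.59	0.03	0.72	0.77
chr16:72828578	ZFHX3	snv	0.23	0.54	0.58	0.17	0.56	0.53
chr19:58420819	ZNF417	snv	0.19	0.56	0.50	0.15	0.41	0.42
chr17:29554310	NF1	snv	0.16	0.56	0.48	0.18	0.12	0.63
chr19:46192605	SNRPD2	snv	0.31	0.58	0.55	0.26	0.62	0.63
chr3:195022735	ACAP2	indel	0.15	0.41	0.55	NA	NA	NA
chr1:201983017	ELF3	indel	0.17	0.15	0.34	NA	NA	NA
chr13:108922263	TNFSF13B	indel	0.17	0.36	0.31	0.21	0.22	0.37
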