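# Bovine rhodopsin-Gi complex: published residue->generic correspondences.
# Chains: R=receptor, A=Galpha(i1), B=Gbeta1.  Columns:
# chain_id	seq_id	icode	generic_label	scheme	segment
R	66	.	12.48	BW	ICL1
R	67	.	12.49	BW	ICL1
A	329	.	H5.01	CGN	alpha5
A	330	.	H5.02	CGN	alpha5
A	331	.	H5.03	CGN	alpha5
A	332	.	H5.04	CGN	alpha5
A	333	.	H5.05	CGN	alpha5
A	334	.	H5.06	CGN	alpha5
A	335	.	H5.07	CGN	alpha5
A	336	.	H5.08	CGN	alpha5
A	337	.	H5.09	CGN	alpha5
A	338	.	H5.10	CGN	alpha5
A	339	.	H5.11	CGN	alpha5
A	340	.	H5.12	CGN	alpha5
A	341	.	H5.13	CGN	alpha5
A	342	.	H5.14	CGN	alpha5
A	343	.	H5.15	CGN	alpha5
A	344	.	H5.16	CGN	alpha5
A	345	.	H5.17	CGN	alpha5
A	346	.	H5.18	CGN	alpha5
A	347	.	H5.19	CGN	alpha5
A	348	.	H5.20	CGN	alpha5
A	349	.	H5.21	CGN	alpha5
A	350	.	H5.22	CGN	alpha5
A	351	.	H5.23	CGN	alpha5
A	352	.	H5.24	CGN	alpha5
A	353	.	H5.25	CGN	alpha5
A	354	.	H5.26	CGN	alpha5
A	256	.	H3.15	CGN	H3
A	257	.	H3.16	CGN	H3
B	271	.	.	.	blade6
B	290	.	.	.	blade6
B	291	.	.	.	blade6
B	312	.	.	.	blade7
B	314	.	.	.	blade7
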