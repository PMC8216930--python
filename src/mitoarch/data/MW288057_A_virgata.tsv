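# Ampittia virgata mitogenome architecture (15333 bp, circular)
# columns: gene, class, from, to, strand, start_codon, stop_codon (1-based inclusive, J-strand coordinates)
gene	class	from	to	strand	start_codon	stop_codon
trnM	tRNA	1	67	J	.	.
trnI	tRNA	67	130	J	.	.
trnQ	tRNA	128	196	N	.	.
nad2	PCG	250	1263	J	ATT	TAA
trnW	tRNA	1262	1328	J	.	.
trnC	tRNA	1321	1385	N	.	.
trnY	tRNA	1395	1460	N	.	.
cox1	PCG	1471	3001	J	CGA	T
trnL2	tRNA	3002	3068	J	.	.
cox2	PCG	3069	3744	J	ATG	T
trnK	tRNA	3745	3815	J	.	.
trnD	tRNA	3827	3893	J	.	.
atp8	PCG	3894	4055	J	ATA	TAA
atp6	PCG	4049	4726	J	ATG	TAA
cox3	PCG	4726	5511	J	ATG	TAA
trnG	tRNA	5514	5577	J	.	.
nad3	PCG	5578	5931	J	ATT	TAA
trnA	tRNA	5939	6005	J	.	.
trnR	tRNA	6005	6067	J	.	.
trnN	tRNA	6068	6133	J	.	.
trnS1	tRNA	6147	6207	J	.	.
trnE	tRNA	6209	6273	J	.	.
trnF	tRNA	6274	6341	N	.	.
nad5	PCG	6342	8076	N	ATT	T
trnH	tRNA	8077	8145	N	.	.
nad4	PCG	8146	9493	N	ATT	T
nad4L	PCG	9484	9771	N	ATG	TAA
trnT	tRNA	9781	9845	J	.	.
trnP	tRNA	9846	9910	N	.	.
nad6	PCG	9913	10443	J	ATT	TAA
cytb	PCG	10446	11594	J	ATA	TAA
trnS2	tRNA	11647	11714	J	.	.
nad1	PCG	11733	12674	N	ATT	TAA
trnL1	tRNA	12675	12743	N	.	.
rrnL	rRNA	12739	14120	N	.	.
trnV	tRNA	14121	14185	N	.	.
rrnS	rRNA	14185	14954	N	.	.
NCR	NCR	14955	15333	J	.	.
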