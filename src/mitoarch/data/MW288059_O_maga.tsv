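# Onryza maga mitogenome architecture (15381 bp, circular)
# columns: gene, class, from, to, strand, start_codon, stop_codon (1-based inclusive, J-strand coordinates)
gene	class	from	to	strand	start_codon	stop_codon
trnM	tRNA	1	68	J	.	.
trnI	tRNA	99	162	J	.	.
trnQ	tRNA	160	228	N	.	.
nad2	PCG	306	1319	J	ATT	TAA
trnW	tRNA	1318	1384	J	.	.
trnC	tRNA	1377	1441	N	.	.
trnY	tRNA	1443	1507	N	.	.
cox1	PCG	1514	3044	J	CGA	T
trnL2	tRNA	3045	3111	J	.	.
cox2	PCG	3112	3787	J	ATG	T
trnK	tRNA	3788	3858	J	.	.
trnD	tRNA	3861	3929	J	.	.
atp8	PCG	3930	4094	J	ATT	TAA
atp6	PCG	4088	4765	J	ATG	TAA
cox3	PCG	4765	5550	J	ATG	TAA
trnG	tRNA	5553	5618	J	.	.
nad3	PCG	5619	5972	J	ATT	TAA
trnA	tRNA	5976	6043	J	.	.
trnR	tRNA	6051	6115	J	.	.
trnN	tRNA	6118	6182	J	.	.
trnS1	tRNA	6186	6246	J	.	.
trnE	tRNA	6249	6317	J	.	.
trnF	tRNA	6319	6383	N	.	.
nad5	PCG	6384	8127	N	ATT	T
trnH	tRNA	8128	8192	N	.	.
nad4	PCG	8193	9531	N	ATG	T
nad4L	PCG	9536	9820	N	ATG	TAA
trnT	tRNA	9826	9890	J	.	.
trnP	tRNA	9891	9955	N	.	.
nad6	PCG	9958	10488	J	ATT	TAA
cytb	PCG	10491	11639	J	ATA	TAA
trnS2	tRNA	11641	11705	J	.	.
nad1	PCG	11728	12666	N	ATG	TAA
trnL1	tRNA	12667	12734	N	.	.
rrnL	rRNA	12794	14175	N	.	.
trnV	tRNA	14176	14240	N	.	.
rrnS	rRNA	14241	15012	N	.	.
NCR	NCR	15013	15381	J	.	.
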