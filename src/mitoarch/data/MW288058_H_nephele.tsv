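# Halpe nephele mitogenome architecture (15291 bp, circular)
# columns: gene, class, from, to, strand, start_codon, stop_codon (1-based inclusive, J-strand coordinates)
gene	class	from	to	strand	start_codon	stop_codon
trnM	tRNA	1	68	J	.	.
trnI	tRNA	69	133	J	.	.
trnQ	tRNA	141	209	N	.	.
nad2	PCG	288	1301	J	ATT	TAA
trnW	tRNA	1300	1366	J	.	.
trnC	tRNA	1359	1423	N	.	.
trnY	tRNA	1425	1490	N	.	.
cox1	PCG	1493	3023	J	CGA	T
trnL2	tRNA	3024	3090	J	.	.
cox2	PCG	3091	3769	J	ATG	T
trnK	tRNA	3770	3840	J	.	.
trnD	tRNA	3845	3914	J	.	.
atp8	PCG	3915	4079	J	ATT	TAA
atp6	PCG	4073	4750	J	ATG	TAA
cox3	PCG	4750	5535	J	ATG	TAA
trnG	tRNA	5538	5604	J	.	.
nad3	PCG	5605	5958	J	ATT	TAA
trnA	tRNA	5967	6032	J	.	.
trnR	tRNA	6038	6103	J	.	.
trnN	tRNA	6106	6172	J	.	.
trnS1	tRNA	6178	6238	J	.	.
trnE	tRNA	6253	6319	J	.	.
trnF	tRNA	6318	6382	N	.	.
nad5	PCG	6383	8123	N	ATT	T
trnH	tRNA	8124	8188	N	.	.
nad4	PCG	8189	9527	N	ATG	T
nad4L	PCG	9534	9818	N	ATG	TAA
trnT	tRNA	9824	9887	J	.	.
trnP	tRNA	9888	9952	N	.	.
nad6	PCG	9955	10485	J	ATT	TAA
cytb	PCG	10485	11636	J	ATG	TAA
trnS2	tRNA	11635	11698	J	.	.
nad1	PCG	11709	12659	N	ATA	TAG
trnL1	tRNA	12663	12730	N	.	.
rrnL	rRNA	12706	14082	N	.	.
trnV	tRNA	14083	14149	N	.	.
rrnS	rRNA	14150	14917	N	.	.
NCR	NCR	14918	15291	J	.	.
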