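gene	category	strand	start	end	start_codon	stop_codon
COI	PCG	J	1	1539	AUA	UAA
ND3	PCG	J	1552	1891	AUU	U
trnL2	tRNA	J	1892	1955
COII	PCG	J	1956	2618	AUU	UAA
trnR	tRNA	J	2664	2718
trnG	tRNA	J	2719	2779
trnD	tRNA	J	2798	2858
trnK	tRNA	J	2897	2957
COIII	PCG	J	2959	3867	AUA	UAA
CR1	CR		3868	4052
trnN	tRNA	J	4053	4117
trnE	tRNA	J	4115	4179
trnQ	tRNA	J	4183	4251
trnA	tRNA	J	4291	4353
trnS1	tRNA	J	4354	4407
trnI	tRNA	J	4409	4477
CYTB	PCG	J	4479	5588	AUA	UAA
trnY	tRNA	N	5650	5586
ND2	PCG	J	5678	6659	AUA	U
trnW	tRNA	J	6660	6722
ND1	PCG	J	6723	7641	AUA	U
trnM	tRNA	J	7642	7702
trnF	tRNA	J	7712	7777
srRNA	rRNA	J	7778	8500
ATP8	PCG	N	8501	8669	AUU	U
ATP6	PCG	J	8696	9346	AUU	UAA
trnL2	tRNA	J	9347	9410
trnT	tRNA	J	9411	9477
CR2	CR		9478	9736
trnP	tRNA	N	9801	9737
ND5	PCG	N	11532	9856	AUA	UAG
trnH	tRNA	N	11592	11533
ND4	PCG	N	12896	11593	AUU	UAA
ND4L	PCG	N	13168	12890	UAG	UAG
trnC	tRNA	J	13207	13267
ND6	PCG	J	13283	13762	AUA	UAA
trnV	tRNA	J	13764	13819
lrRNA	rRNA	J	13820	14902
trnS1	tRNA	J	14903	14965
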