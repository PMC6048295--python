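gene_a	gene_b	relation	ks	ka	ratio_published	mya_published
PheMYB88	OsMYB88	ortholog	0.4394	0.3165	0.7203	33.80
PheMYB3R	LOC_Os07g04700	ortholog	1.3212	0.9278	0.70224	102.00
PheMYB87	OsMYB87	ortholog	0.6579	0.4374	0.664843	50.60
PheMYB2R-28	LOC_Os02g40530	ortholog	0.4018	0.37	0.920856	30.90
PheMYB2R-60	LOC_Os02g41510	ortholog	0.3396	0.2114	0.622497	26.10
PheMYB12	Bradi2g11676.2	ortholog	0.9636	0.8935	0.927252	74.10
PheMYB2R-83	Bradi1g64687.1	ortholog	0.8773	0.625	0.712413	67.50
PheMYB2R-2	Bradi1g60106.1	ortholog	0.601	0.4901	0.815474	46.20
PheMYB2R-33	PheMYB2R-80	paralog	0.1201	0.0769	0.6403	9.24
PheMYB2R-56	PheMYB2R-68	paralog	0.1549	0.1991	1.285345	11.90
PheMYB2R-61	PheMYB2R-74	paralog	0.1119	0.0924	0.825737	8.61
PheMYB2R-54	PheMYB2R-39	paralog	0.169	0.132	0.781065	13.00
PheMYB2R-55	PheMYB2R-78	paralog	0.1941	0.2102	1.082947	14.90
PheMYB2R-4	PheMYB2R-10	paralog	0.0747	0.0809	1.082999	5.75
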