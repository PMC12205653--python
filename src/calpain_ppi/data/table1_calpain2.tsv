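# Consensus ranking of the top 20 alanine-scan mutations at interfacial
# residues of the human calpain-2 heterodimer (CAPN2 PEF(L) / CAPNS1 PEF(S)).
# Averaged over six binding and six folding ddG predictors; energies in kcal/mol.
final_rank	subunit	position	wt_residue	avg_abs_ddg_folding	avg_ddg_binding
1	CAPN2	417	R	0.32	1.15
2	CAPNS1	154	D	0.27	0.97
3	CAPNS1	111	D	0.02	1.02
4	CAPNS1	112	D	0.01	0.96
5	CAPNS1	263	Q	0.46	1.00
6	CAPNS1	118	T	0.26	0.96
7	CAPN2	690	D	0.08	0.68
8	CAPN2	653	D	0.48	0.84
9	CAPN2	7	K	0.03	0.73
10	CAPNS1	119	E	0.27	0.84
11	CAPN2	367	R	0.48	0.75
12	CAPNS1	265	T	0.32	0.80
13	CAPN2	418	R	0.45	0.80
14	CAPN2	420	R	0.27	0.74
15	CAPN2	582	D	0.15	0.76
16	CAPNS1	155	T	0.33	0.73
17	CAPN2	575	E	0.43	0.79
18	CAPNS1	163	E	0.26	0.76
19	CAPN2	661	N	0.47	0.69
20	CAPN2	494	D	0.36	0.60
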