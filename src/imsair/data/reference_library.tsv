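group_id	compound_name	cas_number	form	retention_time_s	relative_drift_time	annotation
1	Ethanol	64-17-5	monomer	73	1.056
1	Ethanol	64-17-5	dimer	73	1.150
2	2-Propanol	67-63-0	monomer	82	1.104
2	2-Propanol	67-63-0	dimer	82	1.203
2	2-Propanol	67-63-0	trimer	82	1.254
3	Propanal	123-38-6	monomer	84	1.058
4	Acetone	67-64-1	monomer	90	1.012
4	Acetone	67-64-1	dimer	90	1.159
4	Acetone	67-64-1	trimer	90	1.205
5	N.I.		monomer	93	1.060	form_imputed
5	N.I.		dimer	93	1.207	form_imputed
6	Propanol	71-23-8	monomer	96	1.123
6	Propanol	71-23-8	dimer	96	1.286
7	Butanal	123-72-8	monomer	113	1.131
7	Butanal	123-72-8	dimer	113	1.333
8	Acetic Acid	64-19-7	monomer	118	1.061
8	Acetic Acid	64-19-7	dimer	118	1.177
9	N.I.		monomer	119	1.049	form_imputed
10	N.I.		monomer	119	1.183	form_imputed
11	Ethyl Acetate	141-78-6	monomer	120	1.121
12	N.I.		monomer	123	1.227	form_imputed
13	2-Butanone	78-93-3	monomer	124	1.081
13	2-Butanone	78-93-3	dimer	124	1.299
14	N.I.		monomer	125	1.061	form_imputed
15	Butanol	71-36-3	monomer	141	1.202
16	N.I.		monomer	145	1.141	form_imputed
17	Pentanal	110-62-3	monomer	166	1.206
18	Propanoic Acid	123-38-6	monomer	170	1.118	cas_printed_as_is
18	Propanoic Acid	123-38-6	dimer	170	1.130	cas_printed_as_is
19	N.I.		monomer	242	1.197	form_imputed
20	2-Hexanone	107-87-9	monomer	262	1.219
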