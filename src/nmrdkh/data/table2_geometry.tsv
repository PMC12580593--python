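# Ti-ligand bond lengths (angstrom) optimized at BLYP/def2-SVP/IEF-PCM(UFF) versus
# X-ray values, for the five complexes used to build the shift protocol. For the
# eta5-Cp ligands the mean Ti-C distance is used. rd_printed is the relative
# deviation as printed (one decimal, percent); two rows round inconsistently with
# the quoted lengths and are kept as printed.
complex_id	bond	calc	expt	rd_printed
Cpx01-[Ti(CO)6]2-	Ti-C	2.07	2.04	1.5
Cpx02-[Ti(CH3)4]	Ti-C	2.10	2.14	1.9
Cpx03-[Ti(Cp)2Cl2]	Ti-Cl	2.37	2.36	0.4
Cpx03-[Ti(Cp)2Cl2]	Ti-C(Cp)	2.45	2.36	3.6
Cpx04-[Ti(Cp)Cl3]	Ti-Cl	2.25	2.22	1.2
Cpx04-[Ti(Cp)Cl3]	Ti-C(Cp)	2.41	2.32	3.9
Ref-[TiCl4]	Ti-Cl	2.20	2.17	1.4
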