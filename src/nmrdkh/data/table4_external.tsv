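# External validation set: nine Ti(IV) complexes not used in the calibration.
# delta_direct: delta(49Ti) from the shielding difference sigma_ref - sigma_calc
#               (GIAO-OLYP/NMR-DKH/IEF-PCM(UFF)).
# delta_model:  delta(49Ti) from the fitted linear model -1.0027*sigma_calc - 1000.0.
# expt:         experimental shift. The neophyl complex is listed at +1375 ppm here;
#               +1325 ppm appears elsewhere in the literature for the same compound.
complex_id	solvent	delta_direct	delta_model	expt
[Ti(OCHMe2)3Cl]	CHCl3	-730	-703	-749
[Ti(OCHMe2)2Cl2]	CHCl3	-632	-605	-598
[Ti(OCHMe2)Cl3]	CHCl3	-354	-327	-358
[Ti(OCMe3)4]	CHCl3	-943	-916	-896
[Ti(OCH(Me)Et)4]	CHCl3	-842	-816	-863
[Ti(OCH2CMe3)4]	CHCl3	-830	-803	-851
[Ti(OCHMe2)3(OCH2CH2NMe2)]	CHCl3	-795	-768	-792
[Ti(NEt2)4]	C6H6	-174	-146	-216
[Ti(CH2C(Me2)(C6H5))4]	C6H6	1203	1235	1375
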