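# Calculated delta(49Ti) (ppm) at GIAO-DFT/NMR-DKH/IEF-PCM(UFF) for 41 Ti(IV) complexes,
# versus experiment. Values as printed (calc: integer ppm; expt: up to one decimal).
# The experimental shift for [Ti(CH3)4] is reported as +1325 ppm here; an alternative
# literature value of +1375 ppm exists for the related neophyl complex (see table4).
complex_id	solvent	mPWLYP	OLYP	BLYP	tHCTH	B97-D3BJ	expt
[Ti(CO)6]2-	CH3CN	-1630	-1608	-1626	-1631	-1635	-1389
[Ti(CH3)4]	CHCl3	1365	1277	1360	1333	1366	1325
[Ti(Cp)2Cl2]	CH2Cl2	-787	-803	-787	-788	-779	-772
[Ti(Cp)Cl3]	CHCl3	-388	-396	-389	-389	-384	-396.5
[Ti(Cp)2Br2]	CH3CN	-642	-664	-643	-642	-631	-668.3
[TiI4]	C6H6	1082	1069	1081	1121	1117	1278.3
[Ti(CH3)2Cl2]	CH2Cl2	877	865	874	904	906	907
[Ti(CH3)3Cl]	CH2Cl2	1167	1117	1163	1168	1184	1188
[Ti(N(CH2CH3)3)Cl]	CHCl3	-204	-192	-204	-203	-202	-171
[Ti(N(CH2CH3)2)4]	CH2Cl2	-205	-197	-205	-210	-208	-224
[TiF6]2-	H2O	-1016	-997	-1015	-1036	-1030	-1160.9
[Ti(Cp)2FCl]	CH2Cl2	-980	-991	-981	-986	-978	-928.3
[Ti(Cp)2ICl]	CH2Cl2	-650	-671	-651	-649	-639	-661.2
[Ti(N(CH3)2)4]	CH2Cl2	-236	-227	-236	-241	-238	-231
[Ti(N(CH2CH2CH3)2)4]	CH2Cl2	-197	-189	-197	-202	-199	-221
[Ti(OCH(CH3)2)4]	CH2Cl2	-865	-835	-863	-862	-865	-859
[Ti(CH3)Cl3]	CH2Cl2	484	491	483	514	509	618
[Ti(CH3)Br3]	CH2Cl2	811	808	809	843	842	825
[TiBr4]	CH2Cl2	441	437	441	456	455	482.9
[Ti(Cp)2I2]	CH2Cl2	-479	-506	-480	-476	-463	-517.2
[Ti(Cp)2BrI]	CH2Cl2	-565	-589	-566	-564	-553	-595.1
[Ti(Cp)2(N3)2]	CHCl3	-1052	-1045	-1051	-1044	-1041	-930.9
[Ti(Cp)2(NCS)2]	CH2Cl2	-1162	-1158	-1161	-1157	-1152	-962.3
[Ti(Cp)Br3]	CHCl3	-102	-117	-103	-98	-92	-123.8
[Ti(Cp)I3]	CH2Cl2	303	280	302	316	323	345.2
[Ti(Me-Cp)Cl3]	CH2Cl2	-329	-339	-330	-329	-323	-332
[Ti(Me-Cp)Br3]	CH2Cl2	-43	-60	-44	-37	-30	-68.8
[Ti(Me-Cp)I3]	CH2Cl2	369	343	367	383	391	399.5
[Ti(Me4-Cp)Cl3]	CH2Cl2	-133	-149	-135	-125	-118	-161.1
[Ti(Me4-Cp)Br3]	CH2Cl2	163	139	160	175	184	123.5
[Ti(Me4-Cp)I3]	CH2Cl2	605	574	602	627	637	589.4
[Ti(Me5-Cp)Cl3]	CHCl3	-101	-120	-103	-96	-87	-85
[Ti(Me5-Cp)Br3]	CHCl3	203	175	199	213	223	186.7
[Ti(SiMe3-Cp)Cl3]	CH2Cl2	-347	-355	-348	-346	-342	-361.4
[Ti(SiMe3-Cp)Br3]	CH2Cl2	-61	-77	-62	-54	-48	-93.2
[Ti(SiMe3-Cp)I3]	CH2Cl2	347	323	345	362	369	373.5
[Ti(SnMe3-Cp)Cl3]	CH2Cl2	-340	-350	-341	-338	-333	-350.1
[Ti(SnMe3-Cp)Br3]	CH2Cl2	-59	-76	-60	-53	-46	-95.4
[Ti((SiMe3)2-Cp)Cl3]	CH2Cl2	-304	-313	-305	-299	-294	-332
[Ti((SiMe3)3-Cp)Cl3]	CH2Cl2	-255	-265	-256	-248	-243	-298
[Ti(Cp)2F2]	CH2Cl2	-1143	-1146	-1143	-1150	-1144	-1036.5
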