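Interval ID	Chromosome	Size [bp]	Start [bp]	End [bp]
A02_GSL_1	chrA02	326909	23675288	24002197
A06_GSL_1	chrA06	90191	16818388	16908579
A09_GSL_1	chrA09	1007698	28668	1036366
A09_GSL_2	chrA09	479317	1465924	1945241
A09_GSL_3	chrA09	73214	2071845	2145059
A09_GSL_4	chrA09	317624	2303455	2621079
A09_GSL_5	chrA09	248198	3036680	3284878
A09_GSL_6	chrA09	395239	3440941	3836180
A09_GSL_7	chrA09	308180	4056024	4364204
A09_GSL_8	chrA09	79540	4580338	4659878
A09_GSL_9	chrA09	270234	6924362	7194596
A09_GSL_10	chrA09	934210	8018931	8953141
A09_GSL_11	chrA09	215209	9150682	9365891
A09_GSL_12	chrA09	173036	9514676	9687712
A09_GSL_13	chrA09	247692	9859341	10107033
A09_GSL_14	chrA09	78703	10831700	10910403
A09_GSL_15	chrA09	117588	10993988	11111576
A09_GSL_16	chrA09	374266	12597247	12971513
A09_GSL_17	chrA09	710703	13041084	13751787
A09_GSL_18	chrA09	378004	16764142	17142146
C02_GSL_1	chrC02	247718	12063724	12311442
C02_GSL_2	chrC02	724820	44411662	45136482
C02_GSL_3	chrC02	431332	45205897	45637229
C07_GSL_1	chrC07	562637	32063223	32625860
C07_GSL_2	chrC07	204488	35236183	35440671
C09_GSL_1	chrC09	671097	1152540	1823637
C09_GSL_2	chrC09	1320909	1911629	3232538
C09_GSL_3	chrC09	195766	3410309	3606075
C09_GSL_4	chrC09	425478	3699696	4125174
C09_GSL_5	chrC09	199414	4285280	4484694
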