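Interval ID	Chromosome	Size [bp]	Start [bp]	End [bp]
A01_SPC_1	chrA01	143410	15427093	15570503
A06_SPC_1	chrA06	247164	8434596	8681760
A06_SPC_2	chrA06	72097	9931989	10004086
A06_SPC_3	chrA06	410672	10177027	10587699
A09_SPC_1	chrA09	41585	33415524	33457109
C03_SPC_1	chrC03	86028	2142025	2228053
C04_SPC_1	chrC04	53519	364385	417904
C04_SPC_2	chrC04	10677	1104377	1115054
C08_SPC_1	chrC08	252499	1743278	1995777
C08_SPC_2	chrC08	2072658	6332262	8404920
C08_SPC_3	chrC08	472053	9033205	9505258
C08_SPC_4	chrC08	464034	12719350	13183384
C08_SPC_5	chrC08	138554	13409507	13548061
C09_SPC_1	chrC09	92091	16262887	16354978
C09_SPC_2	chrC09	381823	17275714	17657537
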