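# BLAST of published RRIM 600 mitochondrial contigs (DDBJ AJJZ01...) against
# the BPM 24 master circle (DDBJ AP014526), 7-column tabular + e-value.
# Minus-strand hits have s.start > s.end.
AJJZ011005169.1	85.93	135	549	683	338566	338700	7e-27
AJJZ011005169.1	96.74	276	937	1211	854221	854495	4e-130
AJJZ011005166.1	98.79	1077	241	1317	21535	20459	0
AJJZ011005166.1	96	200	1	198	1017254	1017055	4e-87
AJJZ010488272.1	100	144	182	325	115093	115236	3e-78
AJJZ010488272.1	96.76	185	51	235	159007	159191	2e-88
AJJZ010488272.1	100	117	1	117	221602	221486	4e-62
AJJZ010386739.1	98.62	217	186	401	179706	179922	4e-112
AJJZ010386739.1	98.3	176	1	176	1031613	1031788	5e-90
AJJZ010369193.1	99.35	308	1	308	423994	424301	4e-171
AJJZ010369193.1	100	203	306	508	663278	663076	3e-113
AJJZ010233339.1	94.44	162	567	728	202461	202622	1e-66
AJJZ010233339.1	82.95	88	415	502	741897	741984	3e-08
AJJZ010233339.1	86.92	107	414	520	882085	882190	1e-19
AJJZ010228768.1	92.62	149	2483	2631	15228	15376	7e-54
AJJZ010228768.1	84.71	327	2631	2934	15404	15728	6e-67
AJJZ010228768.1	82.71	451	1622	2060	357491	357055	9e-66
AJJZ010228768.1	87.14	770	831	1596	358263	357495	0
AJJZ010174367.1	91.99	1548	5871	7413	156744	158290	0
AJJZ010174367.1	92.52	1096	9138	10223	529298	528203	0
AJJZ010174367.1	89.38	885	10204	11068	894891	895774	0
AJJZ010174367.1	94.33	141	11065	11203	895680	895820	3e-40
AJJZ010143874.1	99.97	7965	1	7965	38753	30789	0
AJJZ010143874.1	100	1864	7733	9596	127434	125571	0
AJJZ010142287.1	99.18	612	1	612	338444	339054	0
AJJZ010142287.1	100	585	512	1096	854280	854864	0
AJJZ010039172.1	98.4	187	80	266	17960	17774	6e-97
AJJZ010039172.1	99.6	248	266	513	32045	32292	1e-137
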