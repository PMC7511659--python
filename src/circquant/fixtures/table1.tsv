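name	circ_id	organ	cp_per_ug	sd	library_size	backspliced_sum	size_factor	library_size_excl	backspliced_sum_excl	marker_gene
A	4:4196362-4197112	seedling	70.9	42.5	15.5	299028.5	1256309309.2	34.1	416842.1	32441.5
B	5:1106879-1107381	seedling	75.9	46.3	32.5	639122.0	2401751918.5	56.9	846227.8	62709.9
C	1:382803-383130	seedling	6.3	5.6	4.6	99458.9	392892148.2	8.1	139727.3	10254.1
D	2:19672192-19672380	seedling	8.1	2.3	3.8	75095.2	350726157.6	7.8	103507.7	9207.0
E	1:30349032-30349237	seedling	6.6	7.3	4.2	85267.6	325177084.7	8.2	117946.2	8406.7
F	2:14529841-14530023	seedling	4.4	3.9	1.8	32451.1	107648015.3	3.5	41692.9	2756.1
G	3:3172073-3172253	seedling	8.6	7.7	1.0	17127.8	86565020.0	2.7	23909.8	2232.6
H	2:16614068-16615133	seedling	57.5	36.6	2.2	42413.1	152047044.7	3.9	56545.5	3941.6
A	4:4196362-4197112	root	310.8	58.0	62.8	514242.3	1459154931.5	64.3	515369.2	40115.6
B	5:1106879-1107381	root	403.9	35.5	116.7	984781.5	2670437284.5	119.4	986902.9	73977.9
C	1:382803-383130	root	50.8	8.1	19.8	169589.9	442625591.2	20.2	169930.3	12169.8
D	2:19672192-19672380	root	42.0	8.0	15.8	136481.1	358654044.8	16.2	136774.5	10013.7
E	1:30349032-30349237	root	8.5	3.7	15.1	136987.2	328463657.3	15.3	137248.5	9118.7
F	2:14529841-14530023	root	1.7	3.0	0.4	2450.5	7547596.9	0.4	2458.2	223.8
G	3:3172073-3172253	root	6.7	0.6	4.1	35013.7	84508071.1	4.2	35082.9	2362.5
H	2:16614068-16615133	root	165.7	45.2	1.4	11901.1	30190387.4	1.5	11931.7	895.0
A	4:4196362-4197112	leaf	712.3	103.7	30.1	1260098.8	4104055169.7	58.6	1358140.6	127464.0
B	5:1106879-1107381	leaf	751.1	177.7	33.8	1561949.7	4696612483.6	70.4	1650893.6	145891.2
C	1:382803-383130	leaf	87.5	23.4	5.5	189330.0	568864974.2	8.8	217091.3	17681.0
D	2:19672192-19672380	leaf	43.8	9.6	2.9	121121.1	355550976.4	5.4	133771.1	11041.2
E	1:30349032-30349237	leaf	14.2	12.4	3.2	107435.2	392817341.8	5.3	122590.9	12181.3
F	2:14529841-14530023	leaf	21.5	18.4	1.9	86108.0	186248886.7	3.5	94131.7	5776.3
G	3:3172073-3172253	leaf	13.2	5.6	0.8	35715.0	60958705.1	1.3	40667.9	1886.3
H	2:16614068-16615133	leaf	413.2	111.2	3.1	151191.6	399562884.5	6.4	159512.9	12416.1
A	4:4196362-4197112	flower	966.3	186.2	50.6	518142.0	1815139368.8	65.4	547677.8	52437.1
B	5:1106879-1107381	flower	1095.2	233.1	104.2	1150954.9	3452046537.0	129.6	1215016.1	99180.1
C	1:382803-383130	flower	128.6	48.6	11.7	127251.5	403191198.6	14.8	135097.2	11576.1
D	2:19672192-19672380	flower	42.0	17.0	6.7	79017.3	206880247.3	8.0	83020.7	5931.3
E	1:30349032-30349237	flower	16.0	9.0	11.6	141156.9	382052606.6	13.5	149205.6	11003.1
F	2:14529841-14530023	flower	5.6	9.7	5.1	61782.3	155535658.2	6.1	65279.9	4431.7
G	3:3172073-3172253	flower	12.2	7.2	4.0	42481.2	144215416.7	5.1	44790.1	4178.8
H	2:16614068-16615133	flower	581.3	96.7	9.3	107236.4	329206126.5	11.1	112814.1	9570.6
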