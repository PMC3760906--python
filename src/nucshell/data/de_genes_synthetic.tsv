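# synthetic regulated-gene fixture: per-chromosome up/down tallies
# mirror the reported ideogram pattern; gene ids and bands are invented
gene	chromosome	cytoband	direction
SYNG0001	1	1q11	up
SYNG0002	1	1p12	up
SYNG0003	1	1q13	up
SYNG0004	1	1p14	up
SYNG0005	1	1q15	up
SYNG0006	1	1p16	up
SYNG0007	1	1q17	up
SYNG0008	1	1p18	up
SYNG0009	1	1q11	down
SYNG0010	1	1p12	down
SYNG0011	1	1q13	down
SYNG0012	1	1p14	down
SYNG0013	1	1q15	down
SYNG0014	1	1p16	down
SYNG0015	1	1q17	down
SYNG0016	1	1p18	down
SYNG0017	1	1q19	down
SYNG0018	3	3q11	up
SYNG0019	3	3p12	up
SYNG0020	3	3q13	up
SYNG0021	3	3p14	up
SYNG0022	3	3q15	up
SYNG0023	3	3p16	up
SYNG0024	3	3q17	up
SYNG0025	3	3q11	down
SYNG0026	3	3p12	down
SYNG0027	3	3q13	down
SYNG0028	3	3p14	down
SYNG0029	3	3q15	down
SYNG0030	3	3p16	down
SYNG0031	3	3q17	down
SYNG0032	3	3p18	down
SYNG0033	7	7q11	up
SYNG0034	7	7p12	up
SYNG0035	7	7q13	up
SYNG0036	7	7p14	up
SYNG0037	7	7q15	up
SYNG0038	7	7p16	up
SYNG0039	7	7q17	up
SYNG0040	7	7p18	up
SYNG0041	7	7q11	down
SYNG0042	7	7p12	down
SYNG0043	7	7q13	down
SYNG0044	7	7p14	down
SYNG0045	7	7q15	down
SYNG0046	11	11q11	up
SYNG0047	11	11p12	up
SYNG0048	11	11q13	up
SYNG0049	11	11p14	up
SYNG0050	11	11q15	up
SYNG0051	11	11p16	up
SYNG0052	11	11q17	up
SYNG0053	11	11q11	down
SYNG0054	11	11p12	down
SYNG0055	11	11q13	down
SYNG0056	11	11p14	down
SYNG0057	11	11q15	down
SYNG0058	11	11p16	down
SYNG0059	11	11q17	down
SYNG0060	11	11p18	down
SYNG0061	12	12q11	up
SYNG0062	12	12p12	up
SYNG0063	12	12q13	up
SYNG0064	12	12p14	up
SYNG0065	12	12q15	up
SYNG0066	12	12p16	up
SYNG0067	12	12q11	down
SYNG0068	12	12p12	down
SYNG0069	12	12q13	down
SYNG0070	12	12p14	down
SYNG0071	12	12q15	down
SYNG0072	12	12p16	down
SYNG0073	12	12q17	down
SYNG0074	17	17q11	up
SYNG0075	17	17p12	up
SYNG0076	17	17q13	up
SYNG0077	17	17p14	up
SYNG0078	17	17q15	up
SYNG0079	17	17p16	up
SYNG0080	17	17q17	up
SYNG0081	17	17q11	down
SYNG0082	17	17p12	down
SYNG0083	17	17q13	down
SYNG0084	17	17p14	down
SYNG0085	17	17q15	down
SYNG0086	17	17p16	down
SYNG0087	17	17q17	down
SYNG0088	17	17p18	down
SYNG0089	X	Xq11	up
SYNG0090	X	Xp12	up
SYNG0091	X	Xq13	up
SYNG0092	X	Xp14	up
SYNG0093	X	Xq15	up
SYNG0094	X	Xp16	up
SYNG0095	X	Xq11	down
SYNG0096	X	Xp12	down
SYNG0097	X	Xq13	down
SYNG0098	X	Xp14	down
SYNG0099	X	Xq15	down
SYNG0100	X	Xp16	down
SYNG0101	X	Xq17	down
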