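name	size	es	nes	p_perm	fdr_q	leading_edge
GS_RESPONSIVE	15	0.9914893617	1.680297346	0.03571428571	0.0658436214	RESP012,RESP003,RESP004,RESP001,RESP007,RESP013,RESP006,RESP002,RESP011,RESP005,RESP010,RESP014,RESP015,RESP009,RESP008
GS_RANDOM01	15	-0.3316429201	-1.056559081	0.4166666667	0.6128404669	BG00208,BG00211,BG00145,BG00149
GS_RANDOM02	15	-0.2931829369	-0.8646297079	0.724137931	0.6420233463	BG00214,BG00172,BG00169,BG00158,BG00221
GS_RANDOM03	15	0.3366593024	0.8778447915	0.6956521739	0.817558299	BG00082,BG00202,BG00107,BG00200,BG00108,BG00131,BG00102
GS_RANDOM04	15	0.3687240951	1.120626118	0.347826087	0.6748971193	BG00137,BG00043,BG00136,BG00014
GS_RANDOM05	15	0.2755679488	0.8233484166	0.5833333333	0.695473251	BG00053,BG00048,BG00136,BG00040
GS_RANDOM06	15	-0.3440985565	-1.093787568	0.3181818182	1	BG00011,BG00129,BG00017
GS_RANDOM07	15	-0.300230504	-1.106974168	0.3214285714	1	BG00221,BG00201
GS_RANDOM08	15	-0.3588006259	-1.066299899	0.4615384615	0.7859922179	BG00222,BG00119,BG00113,BG00004
GS_RANDOM09	15	-0.3264915648	-0.882239319	0.6785714286	0.73307393	BG00214,BG00051,BG00196,BG00215,BG00028,BG00069
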