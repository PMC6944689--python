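group	time	n_at_risk	n_events	survival
high	4.961874722	34	1	0.9705882353
high	9.043224747	33	1	0.9411764706
high	15.41279709	32	1	0.9117647059
high	27.2988823	31	1	0.8823529412
high	28.64546758	30	1	0.8529411765
high	31.4423593	29	1	0.8235294118
high	48.7301672	27	1	0.7930283224
high	87.52251253	25	1	0.7613071895
high	95.21443999	24	1	0.7295860566
high	116.3561011	23	1	0.6978649237
high	162.9532465	22	1	0.6661437908
high	172.1852843	21	1	0.634422658
high	179.3374752	20	1	0.6027015251
high	182.4303144	19	1	0.5709803922
high	185.7792527	18	1	0.5392592593
high	195.7014891	17	1	0.5075381264
high	220.841938	16	1	0.4758169935
high	266.9667739	14	1	0.4418300654
high	273.239976	13	1	0.4078431373
high	274.4678092	12	1	0.3738562092
high	309.2300646	11	1	0.339869281
high	312.3602159	10	1	0.3058823529
high	321.0280196	9	1	0.2718954248
high	362.9777067	8	1	0.2379084967
high	428.642747	7	1	0.2039215686
high	471.9714662	6	1	0.1699346405
high	476.0512798	5	1	0.1359477124
high	725.6639093	2	1	0.06797385621
high	795.1047593	1	1	0
low	10.77837313	34	1	0.9705882353
low	23.60229773	33	1	0.9411764706
low	94.44257969	30	1	0.9098039216
low	98.44125821	29	1	0.8784313725
low	101.8338147	28	1	0.8470588235
low	148.6067785	27	1	0.8156862745
low	167.3221007	26	1	0.7843137255
low	174.1556663	25	1	0.7529411765
low	205.9485003	24	1	0.7215686275
low	207.1162788	23	1	0.6901960784
low	239.5773393	22	1	0.6588235294
low	276.0021164	21	1	0.6274509804
low	347.5001574	19	1	0.5944272446
low	408.4656422	18	1	0.5614035088
low	434.5313679	17	1	0.528379773
low	487.2952038	16	1	0.4953560372
low	515.7824859	15	1	0.4623323013
low	659.8886304	13	1	0.4267682782
low	664.6294876	12	1	0.391204255
low	684.4030973	11	1	0.3556402318
low	697.7673765	10	1	0.3200762086
low	724.835483	8	1	0.2800666825
low	789.0814579	7	1	0.2400571565
low	1191.066771	4	1	0.1800428673
low	1340.117032	2	1	0.09002143367
low	1533.690993	1	1	0
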