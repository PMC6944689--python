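compound	n_lines_used	ic50_ratio	mean_log_ic50_high	mean_log_ic50_low	group_test_p	pearson_r	pearson_p	stage_of_exit	ratio_pass	bh_q	hit
compound_01	13	1.641763898	-0.1075329607	-0.3228436621	0.9763436187	0.322174735	0.2830330039	ratio_filter	0		0
compound_02	13	0.5620594237	0.8385974231	1.088815189	0.2051740181	-0.1726876212	0.5726425195	ratio_filter	0		0
compound_03	13	1.453194716	0.01575176875	-0.1465720414	0.6674169688	0.1291815156	0.6740404041	ratio_filter	0		0
compound_04	13	0.8196302477	0.2083925539	0.2947745767	0.4505910569	-0.1180267606	0.7009639742	ratio_filter	0		0
compound_05	13	1.266512588	0.2960064316	0.193396921	0.9706956453	0.1491188596	0.6268147871	ratio_filter	0		0
compound_06	13	0.5410959661	0.1262702787	0.3929959824	0.03140874005	-0.581024041	0.03730313603	ratio_filter	0		0
compound_07	13	0.9362095015	0.5393476834	0.567974639	0.7100946054	0.1509311309	0.6225831079	ratio_filter	0		0
compound_08	13	0.07844281933	-0.3856683057	0.7197784999	0.1962159863	-0.8544011169	0.0001997694052	hit	1	0.0002996541078	1
compound_09	13	0.7608977814	1.414112912	1.532786594	0.236963965	-0.1967685598	0.5193673797	ratio_filter	0		0
compound_10	13	0.5320733378	0.4434134105	0.7174419135	0.2572524624	-0.5357154838	0.0591703855	ratio_filter	0		0
compound_11	13	1.690584906	0.2609735623	0.03293657525	0.2340079425	0.3599626798	0.227002781	ratio_filter	0		0
compound_12	13	1.627634914	-0.4976168989	-0.7091738961	0.2318585983	-0.002911746064	0.9924677017	ratio_filter	0		0
compound_13	13	0.2892755039	0.4043167779	0.9430051191	0.6248475253	-0.3282816652	0.2734805379	ratio_filter	0		0
compound_14	13	0.520654621	-0.1076145078	0.1758357649	0.9478133845	-0.4977188722	0.08349229986	ratio_filter	0		0
compound_15	13	1.048730842	1.462272279	1.441608239	0.8134302273	0.2962545749	0.3256888586	ratio_filter	0		0
compound_16	13	0.7020000193	-0.09292506937	0.06073780658	0.4857557268	-0.3375352986	0.2593705805	ratio_filter	0		0
compound_17	13	2.570500234	1.479913037	1.06989539	0.2711900582	0.04427172433	0.8858095165	ratio_filter	0		0
compound_18	13	0.9050814962	0.3096532366	0.3529655505	0.5747397128	-0.280737301	0.3528377027	ratio_filter	0		0
compound_19	13	0.9453788488	0.0740103451	0.09840446359	0.8445238317	-0.2709499151	0.3705703365	ratio_filter	0		0
compound_20	13	1.599438815	-0.1561854115	-0.3601530427	0.3710721635	0.6028406929	0.02919624987	ratio_filter	0		0
compound_21	13	1.162174942	0.8527256413	0.7874541339	0.7912180048	0.1394197358	0.649638844	ratio_filter	0		0
compound_22	13	0.1123614874	0.03096245382	0.9803449744	0.08079993823	-0.7862232815	0.001436808624	hit	1	0.001436808624	1
compound_23	13	0.9400666091	0.8950919791	0.9219333522	0.20674768	-0.108820284	0.7234314855	ratio_filter	0		0
compound_24	13	0.5312355346	-0.5619700059	-0.2872571234	0.1713286475	-0.1341026368	0.6622731415	ratio_filter	0		0
compound_25	13	1.711817166	1.162072108	0.9286147307	0.4944210766	-0.04409887634	0.8862527419	ratio_filter	0		0
compound_26	13	0.8566572822	-0.08881785238	-0.02162496346	0.2510478315	-0.05333600932	0.8626121062	ratio_filter	0		0
compound_27	13	0.8067169299	0.005146573492	0.09842540229	0.3251947581	-0.04798274227	0.8763011112	ratio_filter	0		0
compound_28	13	0.06705361225	0.1546438253	1.328221647	0.074567831	-0.8671508588	0.0001238141937	hit	1	0.0002996541078	1
compound_29	13	0.8281052392	0.8952007266	0.9771151943	0.5546572825	0.03636546598	0.9061125507	ratio_filter	0		0
compound_30	13	0.7967479137	0.5305355439	0.629214609	0.5336539359	0.02371665444	0.9386991348	ratio_filter	0		0
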