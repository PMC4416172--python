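kmer	shear	buckle	stretch	propeller	stagger	opening
AAA	-0.4271	-9.8425	-0.1684	-7.1021	-0.4541	-2.6067
AAC	0.3791	-5.1436	-0.2963	-10.3664	0.0526	2.1100
AAG	-0.2612	4.1297	-0.0638	-7.0949	0.4943	1.9900
AAT	-0.0778	-6.9272	-0.1724	-5.2553	-0.2040	-1.1313
ACA	-0.0226	3.9027	0.2423	-3.1400	0.0038	-4.3133
ACC	-0.2223	-8.3302	-0.0238	-7.1358	-0.3789	5.8025
ACG	-0.4103	-5.4443	-0.0379	-11.8593	-0.1510	2.4133
ACT	0.1947	-6.5726	-0.2307	-10.2264	0.1512	2.2713
AGA	0.1083	0.0429	0.0423	-17.1936	-0.2085	1.2168
AGC	-0.5859	3.2062	-0.0935	-10.9283	-0.0069	0.9780
AGG	0.7042	-6.3948	0.1683	-5.0541	-0.0710	3.4932
AGT	0.2905	-1.0888	0.1262	-6.1371	-0.0757	0.9532
ATA	-0.2278	9.7317	-0.1164	-8.4315	0.0381	-0.8927
ATC	0.2707	-1.9044	0.0616	-9.3657	0.0969	3.1285
ATG	-0.1401	-4.8949	-0.4084	-1.6619	0.2461	1.1791
ATT	-0.0182	2.3195	-0.1010	-6.8710	0.1666	-1.3174
CAA	0.2367	-1.3418	0.1869	-4.3618	-0.1130	-1.7187
CAC	-0.3770	-4.2101	0.1185	-6.4197	0.2829	4.4964
CAG	0.1728	-10.7743	0.0263	-10.6775	0.2497	2.8931
CAT	0.4197	4.9100	-0.0044	-1.7785	-0.3118	6.9266
CCA	0.3967	-3.4262	-0.2129	-12.9526	0.1330	-0.5800
CCC	-0.0899	0.0047	-0.2040	-12.7847	0.1651	-1.2306
CCG	0.2709	-6.3819	0.0335	-9.7166	0.1933	2.2117
CCT	-0.4865	7.8103	0.2643	-10.9186	0.1094	5.1382
CGA	-0.0475	4.4872	-0.3256	-10.2299	-0.2594	2.7903
CGC	0.1348	5.8853	0.0943	-10.3998	-0.0535	2.2995
CGG	-0.4031	-0.6625	0.0902	-4.0527	-0.4140	6.6610
CGT	-0.0245	2.8075	0.1426	-7.7832	-0.0316	-1.2302
CTA	0.5174	5.3436	-0.1304	-6.5924	0.4058	-2.7438
CTC	0.7854	6.1381	-0.0794	-14.3519	0.1363	-1.2339
CTG	0.2332	1.8743	0.0069	-11.3878	0.1672	0.0494
CTT	0.2486	-0.3714	-0.1541	-3.6617	-0.1027	2.1201
GAA	-0.2877	-2.1569	-0.1844	-12.8153	-0.2031	4.0659
GAC	-0.3628	-4.4919	-0.1325	-3.2859	-0.2141	2.2168
GAG	-0.4237	-5.7929	-0.0106	-12.1227	0.0248	5.5699
GAT	0.1625	2.1602	0.0561	-6.8031	-0.1606	-1.4825
GCA	0.2256	-1.4673	-0.0037	-11.3850	-0.1275	6.7165
GCC	-0.1976	-11.9751	0.0116	-7.2135	0.2289	-1.4361
GCG	-0.3686	-0.9315	-0.1026	-11.5986	-0.3282	4.5122
GCT	0.0773	6.3830	-0.1081	-9.0264	-0.2628	-1.8135
GGA	0.0939	-1.6510	0.1681	-1.3098	-0.1021	2.0298
GGC	-0.0392	-11.1200	-0.0082	-9.5011	-0.0200	1.1527
GGG	0.3810	-0.7461	-0.0124	0.1472	-0.0259	2.5527
GGT	-0.0279	4.7098	0.1404	-9.8352	-0.2793	3.2543
GTA	-0.0198	1.2120	0.1858	-12.7031	0.0388	0.3604
GTC	-0.3325	-2.5684	0.1909	-7.6998	-0.0259	0.7995
GTG	0.0408	11.0897	0.0609	-9.6360	0.0709	1.7173
GTT	0.4041	11.3997	-0.0075	-0.9739	-0.2166	-2.9150
TAA	0.0183	-0.5906	0.0434	-4.5563	0.0490	-1.1937
TAC	0.0213	4.8807	0.0269	-3.2749	0.0442	-3.8732
TAG	0.1301	2.3550	0.2096	-5.4733	-0.1321	1.0158
TAT	0.0832	4.6887	0.0438	1.8840	-0.0437	7.6665
TCA	0.1591	8.7196	0.0958	-4.8228	-0.1112	3.2239
TCC	0.1610	4.9211	-0.0042	-5.8746	0.2713	-1.5963
TCG	0.1855	0.5262	0.2057	-11.3176	-0.6239	-1.1231
TCT	-0.2385	-3.9210	-0.3079	-11.6372	-0.2895	3.9277
TGA	0.0900	-4.8713	0.0571	-7.2631	-0.3412	-0.4232
TGC	-0.4808	-0.1532	0.1133	-4.0090	-0.0756	-3.8254
TGG	0.0800	6.9491	-0.1739	-3.5322	-0.1357	-2.0687
TGT	-0.3785	1.8031	0.3225	-11.7760	-0.0822	-2.1628
TTA	-0.0214	0.3183	-0.0225	-5.8744	0.1438	-2.0642
TTC	0.1422	1.5436	-0.0242	-7.2266	-0.3265	3.0279
TTG	-0.1245	0.2145	-0.1619	-12.4731	-0.1691	1.2121
TTT	0.0293	3.2834	0.1317	-5.9526	-0.0446	-3.4659
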