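ch	a_n_snps	a_start	a_end	a_pmin_snp	a_pmin	b_n_snps	b_start	b_end	b_pmin_snp	b_pmin	genes
1	9	28084237	28106641	rs6679432	1.94E-02	4	28085800	28094024	rs17257252	4.41E-03	C1orf38, RPA2
1	5	160357908	160384670	rs1337072	1.36E-02	4	160382664	160395446	rs12124105	1.52E-02	NOS1AP
1	5	182071303	182087392	rs10494570	1.11E-02	7	182079430	182107726	rs11806497	5.41E-04	RGL1
1	4	212649607	212665577	rs10779614	1.19E-02	4	212650752	212655224	rs17022866	2.21E-03	PTPN14
2	4	166129660	166148793	rs10803799	1.16E-04	4	166123345	166130256	rs16850914	3.41E-03	FAM130A2
2	4	240548770	240568964	rs11893710	6.42E-03	4	240542948	240556386	rs13424612	1.19E-03	NDUFA10
3	8	14469859	14483315	rs11128699	6.25E-03	5	14470459	14486703	rs17237132	1.77E-03	SLC6A6
3	4	16380744	16383669	rs9835911	5.03E-03	4	16377563	16389202	rs689953	1.43E-02	RFTN1
3	7	21726437	21747061	rs957589	1.32E-03	8	21717029	21737614	rs13077624	1.02E-02	ZNF385D
3	7	41451566	41467634	rs1495692	4.32E-05	7	41447475	41465298	rs12054014	2.48E-03	ULK4
3	5	62635606	62643369	rs978879	8.10E-03	6	62615383	62637642	rs1512015	1.31E-03	CADPS
3	4	144385643	144403567	rs6776634	3.98E-02	11	144384755	144408513	rs6786129	6.79E-04	PBX2P1
4	9	93699740	93730844	rs7682842	5.98E-04	9	93684320	93699740	rs17319672	8.72E-06	GRID2
4	9	93699740	93730844	rs7682842	5.98E-04	4	93719692	93727390	rs17019608	3.45E-03	GRID2
5	5	7574083	7602448	rs10035541	1.85E-02	7	7591237	7615180	rs1392481	2.56E-03	ADCY2
5	5	41608479	41624460	rs669684	8.81E-03	10	41575032	41617270	rs620876	4.99E-03	TCP1L2
5	4	148176930	148194422	rs12652757	5.08E-03	4	148169604	148179324	rs2116714	2.06E-03	ADRB2
5	4	167355762	167368572	rs17069578	1.99E-03	5	167361210	167387579	rs17069636	2.93E-04	ODZ2
6	4	12225330	12232841	rs2228213	1.71E-02	4	12225541	12239453	rs2327514	2.36E-03	HIVEP1
6	4	31234388	31247483	rs1108746	9.83E-04	4	31230976	31243685	rs9501063	2.86E-03	CCHCR1, POU5F1, TCF19
6	10	32278411	32307330	rs2071287	1.22E-02	6	32288098	32302370	rs2269418	4.43E-04	NOTCH4
6	7	46016169	46032945	rs4714892	5.78E-04	10	45987042	46031767	rs9367228	9.12E-03	CLIC5
6	6	129830351	129839777	rs6569603	1.91E-04	6	129838313	129856864	rs17057464	2.75E-03	LAMA2
6	5	147933198	147957929	rs7743538	6.08E-03	5	147940910	147969453	rs9497816	3.43E-03	SAMD5
6	6	148834310	148848906	rs1124163	3.87E-03	5	148822606	148840150	rs6927662	3.53E-03	SASH1
6	7	168744759	168766408	rs12197584	4.58E-03	4	168765804	168776041	rs9456259	6.38E-03	SMOC2
7	4	37749625	37757420	rs2709114	5.41E-03	6	37754332	37786876	rs2709114	3.52E-03	GPR141
7	10	154494400	154529011	rs1619015	2.17E-03	4	154510872	154528905	rs1730186	1.82E-02	HTR5A
8	5	1466441	1477325	rs17748677	3.40E-03	4	1468372	1478011	rs17681530	3.86E-03	DLGAP2
8	6	3543065	3557725	rs17326670	2.39E-03	6	3537344	3551589	rs17067079	9.79E-06	CSMD1
8	4	4194159	4209292	rs10104910	9.77E-03	4	4200701	4215192	rs3990909	5.21E-03	CSMD1
8	6	17266781	17290933	rs12676388	8.09E-03	4	17281156	17285461	rs7460082	2.31E-02	MTMR7
8	5	72347452	72360941	rs11991562	1.34E-02	8	72351592	72382875	rs6989867	8.03E-04	EYA1
8	4	102824050	102836428	rs6468792	2.12E-02	7	102818744	102835352	rs1125334	2.81E-03	NCALD
8	6	139357180	139371129	rs1512406	5.04E-04	7	139358561	139377143	rs1512407	7.92E-05	FAM135B
8	5	141035897	141054146	rs6981165	3.17E-03	5	141032458	141044168	rs881378	2.54E-03	NIBP
9	4	7155427	7162630	rs10976082	1.43E-02	4	7140997	7157510	rs913581	7.73E-04	JMJD2C
9	4	9408277	9423131	rs4342663	8.69E-03	13	9383744	9435270	rs10816124	7.94E-04	PTPRD, RN7SLP2
9	7	118770530	118810301	rs7042036	3.43E-04	6	118810026	118836028	rs2050274	3.15E-03	ASTN2
10	4	66260831	66274062	rs1227244	1.90E-02	7	66245561	66275840	rs10761866	1.42E-03	ANXA2P3
10	16	74499314	74567822	rs12573512	5.00E-03	9	74540513	74570789	rs6480671	1.23E-03	ECD, NUDT13
10	4	90564031	90575327	rs11817978	1.33E-02	4	90570124	90575118	rs4934423	2.08E-02	ANKRD22, LIPM
10	5	115300542	115311814	rs4918842	1.77E-02	6	115301876	115327383	rs7093962	6.99E-03	HABP2
10	6	135216408	135227438	rs8181425	1.50E-02	4	135209148	135223425	rs9629977	1.94E-03	FLJ44653, SYCE1
11	5	12253357	12271091	rs7106205	1.43E-03	5	12241317	12255138	rs11022270	9.33E-03	MICALCL
11	4	20620979	20632993	rs1617769	2.17E-03	7	20586739	20621980	rs2298826	1.57E-04	SLC6A5
11	4	87727005	87740895	rs4753359	1.68E-03	4	87719881	87730124	rs618143	9.42E-03	CTSC
11	6	88091682	88116810	rs1993842	9.39E-03	5	88095026	88109123	rs2892293	4.54E-03	GRM5
11	4	92259078	92271738	rs9666789	1.52E-02	5	92259808	92275974	rs12421052	2.14E-03	FAT3
11	4	122111119	122121536	rs4935804	2.30E-03	4	122121115	122128473	rs1540113	1.29E-03	UBASH3B
12	5	65221347	65236556	rs10748053	8.18E-04	4	65208873	65229384	rs7971370	4.95E-03	GRIP1
12	4	71010301	71018781	rs10506653	1.09E-02	10	70989581	71025118	rs17783131	6.08E-04	TRHDE
13	17	94683173	94714801	rs4258481	7.94E-03	13	94684855	94734859	rs9590213	1.54E-04	ABCC4
13	5	102501056	102512255	rs157382	1.01E-02	12	102491230	102519109	rs1549836	2.17E-03	SLC10A2
13	4	108262545	108277505	rs9521065	1.24E-03	4	108262052	108276593	rs390790	7.41E-03	MYO16
14	6	85039659	85062024	rs1884009	1.20E-03	4	85043508	85064044	rs17709714	1.19E-03	FLRT2
14	9	85074724	85098018	rs1955418	2.29E-03	4	85086089	85096268	rs985620	1.98E-04	FLRT2
15	4	24767181	24769395	rs28551016	8.86E-04	4	24761221	24768832	rs4887529	1.07E-03	GABRA5
16	4	81469875	81483050	rs16958826	1.42E-03	14	81469724	81505974	rs9319578	5.41E-05	CDH13
19	5	11815562	11851258	rs286246	2.12E-03	4	11816632	11836425	rs1466308	8.54E-03	VN2R13P, VN2R14P, ZNF439, ZNF440
20	4	6702246	6720263	rs235704	5.80E-03	4	6714019	6722420	rs13044579	5.60E-03	BMP2
20	6	19983767	20012701	rs6046593	8.04E-03	5	19997088	20023996	rs9808594	5.69E-04	C20orf26
20	10	48907768	48942090	rs1062651	9.85E-04	4	48912167	48930175	rs6096138	5.45E-03	BCAS4
20	5	54252037	54262859	rs6099057	1.10E-03	7	54233123	54261400	rs6123568	4.10E-03	MC3R
21	7	26422204	26447377	rs12482753	4.85E-03	12	26419368	26465912	rs9984764	1.61E-03	APP
21	6	40435728	40454200	rs2837468	1.36E-02	6	40446501	40459247	rs11911749	3.25E-04	DSCAM
22	6	15695102	15706432	rs165611	1.02E-04	5	15689881	15706432	rs2075120	1.62E-04	CECR8
22	4	29185674	29194610	rs5753158	6.46E-03	10	29169346	29215980	rs5753152	2.18E-04	SEC14L3
22	11	35727496	35747143	rs6000529	1.11E-02	5	35733248	35738081	rs130598	7.85E-03	C22orf33, MPST, TST
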