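label	fluorochrome	start_mb	end_mb	n_oligos	chromosome	origin	span_kb	density_per_kb
Red	Atto550	5	6	1997	A03	A03	1000	2.0
Red	Atto550	34.9	36	2253	A05	A05	1010	2.2
Red	Atto550	20	21	3858	A06	A06	1000	3.9
Red	Atto550	10	11	2976	A09	A09	1000	3.0
Red	Atto550	37.8	38.3	2245	B01	A05	500	4.5
Red	Atto550	10.8	11.6	1287	B04	A09	800	1.6
Red	Atto550	17.3	18.3	1361	B04	A06	1000	1.4
Red	Atto550	4.5	6.1	2000	B08	A03	1600	1.3
Red	Atto550	4.7	6.2	1530	C03	A03	1500	1.0
Red	Atto550	14.2	15.5	2393	C05	A06	1300	1.8
Red	Atto550	33.9	34.4	653	C09	A09	500	1.3
Red	Atto550	2.1	3.5	1003	R03	A03	1400	0.7
Red	Atto550	36.9	38.1	1294	R05	A05	1200	1.1
Red	Atto550	16.7	17.3	1006	R06	A06	600	1.7
Red	Atto550	5.1	5.8	1063	R09	A09	700	1.5
Green	Atto488	4	4.5	5420	A01-1	A01-1	500	10.8
Green	Atto488	29.5	30	4615	A01-2	A01-2	500	9.2
Green	Atto488	2	2.5	4512	A04	A04	500	9.0
Green	Atto488	12	12.5	3906	A05	A05	500	7.8
Green	Atto488	4	4.5	4794	A09-1	A09-1	500	9.6
Green	Atto488	40	40.5	3853	A09-2	A09-2	500	7.7
Green	Atto488	4	4.45	2023	B05	A01-1	450	4.5
Green	Atto488	17.5	18	1057	B06-1	A05	500	2.1
Green	Atto488	33.9	34.2	1076	B06-2	A04	300	3.6
Green	Atto488	2.9	3.3	1225	B07-1	A01-2	400	3.1
Green	Atto488	10.3	10.9	1453	B07-2	A09-1	600	2.4
Green	Atto488	44.6	45.25	1060	B08	A09-2	600	1.8
Green	Atto488	4.4	5.2	4020	C01-1	A01-1	800	5.0
Green	Atto488	34.7	35	1759	C01-2	A01-1	300	5.9
Green	Atto488	9.2	10	2119	C04-1	A04	800	2.6
Green	Atto488	16.9	17.6	1844	C04-2	A05	700	2.6
Green	Atto488	21.9	22	583	C04-3	A04	100	5.8
Green	Atto488	26.7	27.3	2667	C08	A09-2	600	4.4
Green	Atto488	3.75	4	1513	C09	A09-1	250	6.1
Green	Atto488	4.5	5	973	R01	A05	500	1.9
Green	Atto488	11.7	12.1	954	R01	A09-2	400	2.4
Green	Atto488	45.3	46	1167	R01	A01-2	700	1.7
Green	Atto488	1.5	1.9	1646	R02	A01-1	400	4.1
Green	Atto488	46.7	47.5	940	R04	A04	800	1.2
Green	Atto488	4.7	5.1	1030	R09	A09-1	400	2.6
Yellow	Atto594	34	35	2291	A06	A06	1000	2.3
Yellow	Atto594	25	26	2495	A07	A07	1000	2.5
Yellow	Atto594	4	5	2225	A10-1	A10-1	1000	2.2
Yellow	Atto594	15	16	2280	A10-2	A10-2	1000	2.3
Yellow	Atto594	31.8	32.9	2271	B02-1	A10-2	1100	2.1
Yellow	Atto594	41.1	41.8	2281	B02-2	A06	700	3.3
Yellow	Atto594	24.5	26	2478	B03	A07	1500	1.7
Yellow	Atto594	4.3	5.2	1219	C06-1	A07	900	1.4
Yellow	Atto594	38.3	39.2	1233	C06-2	A10-1	900	1.4
Yellow	Atto594	33.5	34.9	1827	C07	A06	1400	1.3
Yellow	Atto594	36	37.5	1840	C09	A10-2	1500	1.2
Yellow	Atto594	9	10.4	1232	R04	A06	1400	0.9
Yellow	Atto594	19.1	20.2	1210	R07	A10-2	1100	1.1
Yellow	Atto594	28.3	29.6	1320	R09	A07	1300	1.0
FarRed	Cy5	5	6	4897	A02-1	A02-1	1000	4.9
FarRed	Cy5	25	26	3489	A02-2	A02-2	1000	3.5
FarRed	Cy5	25	26	2494	A07	A07	1000	2.5
FarRed	Cy5	2	3	2473	A08-1	A08-1	1000	2.5
FarRed	Cy5	12	13	2959	A08-2	A08-2	1000	3.0
FarRed	Cy5	24.3	26	2486	B03	A07	1700	1.5
FarRed	Cy5	3	3.5	1172	B04	A02-2	500	2.3
FarRed	Cy5	21.5	23.2	1334	B05	A02-1	1700	0.8
FarRed	Cy5	20.9	22	1183	B07	A08-2	1100	1.1
FarRed	Cy5	6.8	7.9	3295	C02-1	A02-1	1100	3.0
FarRed	Cy5	38.7	40.3	2214	C02-2	A02-2	1600	1.4
FarRed	Cy5	4.3	5.2	1218	C06-1	A07	900	1.4
FarRed	Cy5	6.2	7.5	1781	C06-2	A08-2	1300	1.4
FarRed	Cy5	0.3	1.1	656	C08	A08-1	800	0.8
FarRed	Cy5	34.8	35.7	986	R01	A02-2	900	1.1
FarRed	Cy5	15.7	17	1250	R02	A02-1	1300	1.0
FarRed	Cy5	11.9	12.8	909	R08	A08-1	900	1.0
FarRed	Cy5	28.3	29.6	1319	R09	A07	1300	1.0
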