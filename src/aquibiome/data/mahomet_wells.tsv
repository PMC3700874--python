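well	temp_c	ph	spec_cond_us_cm	so4_mm	ch4_um	h2_nm	dic_mm	doc_mg_l
Chm94B	13.7	7.5	707	0.58	< 0.2	25	7.8	2.2
Chm96A	13.8	7.5	663	0.41	1	3	7.2	1.3
Frd94A	14.2	7.5	760	0.98	2	3	7.4	< 0.4
Iro95A	14.3	7.5	943	1.50	1	60	n/a	3.3
Iro96A	12.1	7.5	1254	4.23	1	n/a	n/a	n/a
Iro98B	13.0	7.6	1277	4.68	3	10	6.6	43.0
Iro98D	13.6	7.8	759	0.72	19	180	7.9	1.9
Ver94A	14.4	7.5	1279	4.57	2	n/a	6.7	1.8
Ver94B	13.7	7.3	1893	10.73	1	89	4.8	1.1
Chm94A	14.1	7.6	651	0.07	4	n/a	8.0	3.6
Chm95A	14.0	7.6	649	0.14	8	4	7.7	2.1
Chm95B	13.8	7.9	670	0.04	30	3	7.9	2.0
Chm95C	13.7	7.7	601	0.11	3	20	6.6	0.5
Frd94B	15.4	7.6	611	0.05	43	9	7.4	< 0.4
Iro98C	13.3	7.4	664	0.04	15	66	7.6	2.3
Ver94C	13.6	7.7	616	0.23	3	46	7.4	1.1
Ver94D	13.9	7.7	621	0.18	10	n/a	7.7	0.8
AnderN	14.8	7.6	617	0.02	91	144	6.6	n/a
AnderS	15.1	7.1	860	0.02	1237	175	25.9	n/a
CardiS	13.6	7.7	645	0.03	454	240	7.5	n/a
Chm95D	14.0	7.8	625	< 0.01	220	12	7.6	1.6
Chm98A	13.7	7.7	714	< 0.01	676	24	7.9	4.2
PklndE	14.6	7.6	678	0.03	221	63	8.7	n/a
PklndW	14.4	7.5	725	0.03	611	100	6.0	n/a
RailRd	14.4	7.7	661	0.02	106	50	6.4	n/a
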