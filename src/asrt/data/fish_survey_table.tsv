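probe	chrom	population	sd_percent	n_nuclei	classification
RP23-341D14	chr3	E-5	56	57	asynchronous
RP23-341D14	chr3	C2	58	31	asynchronous
RP23-235F22	chr3	E-5	45	95	asynchronous
RP23-317D10	chr3	E-5	51	60	asynchronous
RP23-317D10	chr3	C2	42	87	asynchronous
RP23-317D10	chr3	ES	50	109	asynchronous
RP23-115D3	chr3	E-5	42	90	asynchronous
RP23-115D3	chr3	C2	42	88	asynchronous
RP23-115D3	chr3	ES	43	108	asynchronous
RP23-439A9	chr4	E-5	54	55	asynchronous
RP23-439A9	chr4	C2	51	76	asynchronous
RP23-439A9	chr4	B4	38	96	asynchronous
RP23-439A9	chr4	ES	50	100	asynchronous
RP23-439A9	chr4	MEF	40	102	asynchronous
RP23-439A9	chr4	YC	38	76	asynchronous
RP24-100L23	chr6	E-5	59	117	asynchronous
RP24-100L23	chr6	C2	39	104	asynchronous
RP24-100L23	chr6	B4	47	104	asynchronous
RP24-100L23	chr6	ES	57	116	asynchronous
RP24-100L23	chr6	MEF	58	68	asynchronous
RP24-318I18	chr8	E-5	58	78	asynchronous
RP24-318I18	chr8	C2	56	79	asynchronous
RP24-318I18	chr8	B4	40	87	asynchronous
RP24-318I18	chr8	ES	35	101	asynchronous
RP24-318I18	chr8	MEF	52	106	asynchronous
RP24-83L7	chr4	E-5	52	96	asynchronous
RP24-83L7	chr4	C2	58	52	asynchronous
RP24-83L7	chr4	ES	45	103	asynchronous
RP24-83L7	chr4	MEF	48	108	asynchronous
RP24-83L7	chr4	YC	50	103	asynchronous
RP23-182L17	chr8	E-5	38	32	asynchronous
RP23-182L17	chr8	B4	41	92	asynchronous
RP23-182L17	chr8	ES	44	110	asynchronous
RP23-182L17	chr8	MEF	47	103	asynchronous
RP23-326K16	chr16	E-5	53	76	asynchronous
RP23-326K16	chr16	B4	47	74	asynchronous
RP23-326K16	chr16	ES	42	96	asynchronous
RP23-326K16	chr16	MEF	61	96	asynchronous
RP23-326K16	chr16	YC	50	79	asynchronous
RP23-38D22	chr16	E-5	53	43	asynchronous
RP23-38D22	chr16	C2	57	65	asynchronous
RP23-38D22	chr16	B4	59	105	asynchronous
RP23-38D22	chr16	ES	50	112	asynchronous
RP23-38D22	chr16	MEF	57	104	asynchronous
RP23-38D22	chr16	YC	44	89	asynchronous
RP24-386G17	chr12	C2	54	56	asynchronous
RP24-386G17	chr12	B4	47	103	asynchronous
RP24-386G17	chr12	ES	47	96	asynchronous
RP24-386G17	chr12	MEF	47	101	asynchronous
RP23-13F5	chr12	E-5	46	103	asynchronous
RP23-13F5	chr12	C2	43	91	asynchronous
RP23-13F5	chr12	B4	47	105	asynchronous
RP23-13F5	chr12	ES	52	109	asynchronous
RP23-13F5	chr12	MEF	52	65	asynchronous
RP23-333P23	chr12	E-5	52	57	asynchronous
RP23-333P23	chr12	C2	39	84	asynchronous
RP23-63H2	chr4	E-5	55	88	asynchronous
RP23-59I11	chr16	E-5	50	83	asynchronous
RP23-68K13	chr6	E-5	23	81	synchronous
RP23-68K13	chr6	C2	10	109	synchronous
RP23-68K13	chr6	B4	18	100	synchronous
RP23-68K13	chr6	ES	12	108	synchronous
RP23-68K13	chr6	MEF	21	95	synchronous
RP23-68K13	chr6	YC	23	104	synchronous
RP24-353L13	chr13	E-5	15	100	synchronous
RP24-353L13	chr13	C2	11	100	synchronous
RP24-353L13	chr13	B4	13	97	synchronous
RP24-353L13	chr13	ES	18	101	synchronous
RP24-353L13	chr13	MEF	10	106	synchronous
RP23-81A7	chr15	E-5	17	101	synchronous
RP23-81A7	chr15	C2	20	102	synchronous
RP23-81A7	chr15	B4	12	101	synchronous
RP23-81A7	chr15	ES	17	100	synchronous
RP23-81A7	chr15	MEF	10	106	synchronous
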