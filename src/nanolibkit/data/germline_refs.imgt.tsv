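germline	residue_index	imgt_position
IGHV3-3*01	0	1
IGHV3-3*01	1	2
IGHV3-3*01	2	3
IGHV3-3*01	3	4
IGHV3-3*01	4	5
IGHV3-3*01	5	6
IGHV3-3*01	6	7
IGHV3-3*01	7	8
IGHV3-3*01	8	9
IGHV3-3*01	9	11
IGHV3-3*01	10	12
IGHV3-3*01	11	13
IGHV3-3*01	12	14
IGHV3-3*01	13	15
IGHV3-3*01	14	16
IGHV3-3*01	15	17
IGHV3-3*01	16	18
IGHV3-3*01	17	19
IGHV3-3*01	18	20
IGHV3-3*01	19	21
IGHV3-3*01	20	22
IGHV3-3*01	21	23
IGHV3-3*01	22	24
IGHV3-3*01	23	25
IGHV3-3*01	24	26
IGHV3-3*01	25	27
IGHV3-3*01	26	28
IGHV3-3*01	27	29
IGHV3-3*01	28	30
IGHV3-3*01	29	35
IGHV3-3*01	30	36
IGHV3-3*01	31	37
IGHV3-3*01	32	38
IGHV3-3*01	33	39
IGHV3-3*01	34	40
IGHV3-3*01	35	41
IGHV3-3*01	36	42
IGHV3-3*01	37	43
IGHV3-3*01	38	44
IGHV3-3*01	39	45
IGHV3-3*01	40	46
IGHV3-3*01	41	47
IGHV3-3*01	42	48
IGHV3-3*01	43	49
IGHV3-3*01	44	50
IGHV3-3*01	45	51
IGHV3-3*01	46	52
IGHV3-3*01	47	53
IGHV3-3*01	48	54
IGHV3-3*01	49	55
IGHV3-3*01	50	56
IGHV3-3*01	51	57
IGHV3-3*01	52	58
IGHV3-3*01	53	59
IGHV3-3*01	54	62
IGHV3-3*01	55	63
IGHV3-3*01	56	64
IGHV3-3*01	57	65
IGHV3-3*01	58	66
IGHV3-3*01	59	67
IGHV3-3*01	60	68
IGHV3-3*01	61	69
IGHV3-3*01	62	70
IGHV3-3*01	63	71
IGHV3-3*01	64	72
IGHV3-3*01	65	74
IGHV3-3*01	66	75
IGHV3-3*01	67	76
IGHV3-3*01	68	77
IGHV3-3*01	69	78
IGHV3-3*01	70	79
IGHV3-3*01	71	80
IGHV3-3*01	72	81
IGHV3-3*01	73	82
IGHV3-3*01	74	83
IGHV3-3*01	75	84
IGHV3-3*01	76	85
IGHV3-3*01	77	86
IGHV3-3*01	78	87
IGHV3-3*01	79	88
IGHV3-3*01	80	89
IGHV3-3*01	81	90
IGHV3-3*01	82	91
IGHV3-3*01	83	92
IGHV3-3*01	84	93
IGHV3-3*01	85	94
IGHV3-3*01	86	95
IGHV3-3*01	87	96
IGHV3-3*01	88	97
IGHV3-3*01	89	98
IGHV3-3*01	90	99
IGHV3-3*01	91	100
IGHV3-3*01	92	101
IGHV3-3*01	93	102
IGHV3-3*01	94	103
IGHV3-3*01	95	104
IGHV3S53*01	0	1
IGHV3S53*01	1	2
IGHV3S53*01	2	3
IGHV3S53*01	3	4
IGHV3S53*01	4	5
IGHV3S53*01	5	6
IGHV3S53*01	6	7
IGHV3S53*01	7	8
IGHV3S53*01	8	9
IGHV3S53*01	9	11
IGHV3S53*01	10	12
IGHV3S53*01	11	13
IGHV3S53*01	12	14
IGHV3S53*01	13	15
IGHV3S53*01	14	16
IGHV3S53*01	15	17
IGHV3S53*01	16	18
IGHV3S53*01	17	19
IGHV3S53*01	18	20
IGHV3S53*01	19	21
IGHV3S53*01	20	22
IGHV3S53*01	21	23
IGHV3S53*01	22	24
IGHV3S53*01	23	25
IGHV3S53*01	24	26
IGHV3S53*01	25	27
IGHV3S53*01	26	28
IGHV3S53*01	27	29
IGHV3S53*01	28	30
IGHV3S53*01	29	35
IGHV3S53*01	30	36
IGHV3S53*01	31	37
IGHV3S53*01	32	38
IGHV3S53*01	33	39
IGHV3S53*01	34	40
IGHV3S53*01	35	41
IGHV3S53*01	36	42
IGHV3S53*01	37	43
IGHV3S53*01	38	44
IGHV3S53*01	39	45
IGHV3S53*01	40	46
IGHV3S53*01	41	47
IGHV3S53*01	42	48
IGHV3S53*01	43	49
IGHV3S53*01	44	50
IGHV3S53*01	45	51
IGHV3S53*01	46	52
IGHV3S53*01	47	53
IGHV3S53*01	48	54
IGHV3S53*01	49	55
IGHV3S53*01	50	56
IGHV3S53*01	51	57
IGHV3S53*01	52	58
IGHV3S53*01	53	59
IGHV3S53*01	54	63
IGHV3S53*01	55	64
IGHV3S53*01	56	65
IGHV3S53*01	57	66
IGHV3S53*01	58	67
IGHV3S53*01	59	68
IGHV3S53*01	60	69
IGHV3S53*01	61	70
IGHV3S53*01	62	71
IGHV3S53*01	63	72
IGHV3S53*01	64	74
IGHV3S53*01	65	75
IGHV3S53*01	66	76
IGHV3S53*01	67	77
IGHV3S53*01	68	78
IGHV3S53*01	69	79
IGHV3S53*01	70	80
IGHV3S53*01	71	81
IGHV3S53*01	72	82
IGHV3S53*01	73	83
IGHV3S53*01	74	84
IGHV3S53*01	75	85
IGHV3S53*01	76	86
IGHV3S53*01	77	87
IGHV3S53*01	78	88
IGHV3S53*01	79	89
IGHV3S53*01	80	90
IGHV3S53*01	81	91
IGHV3S53*01	82	92
IGHV3S53*01	83	93
IGHV3S53*01	84	94
IGHV3S53*01	85	95
IGHV3S53*01	86	96
IGHV3S53*01	87	97
IGHV3S53*01	88	98
IGHV3S53*01	89	99
IGHV3S53*01	90	100
IGHV3S53*01	91	101
IGHV3S53*01	92	102
IGHV3S53*01	93	103
IGHV3S53*01	94	104
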