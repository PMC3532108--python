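position	A	C	G	T
-5	63	13	15	80
-4	45	32	30	64
-3	84	5	3	79
-2	78	23	9	61
-1	79	18	14	60
T1	96	25	35	15
T2	37	4	3	127
T3	117	4	8	42
T4	17	26	19	109
+1	57	13	21	80
+2	62	10	22	77
+3	78	4	4	85
+4	59	30	34	48
+5	68	18	14	71
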