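feature_id	SS_D1	BS_D1	SO_D1	SS_D4	BS_D4	SO_D4	SS_D8	BS_D8	SO_D8	SS_D11	BS_D11	SO_D11	SS_D15	BS_D15	SO_D15	SS_D19	BS_D19	SO_D19
A01	10	5	0	10	5	0	10	5	0	10	5	0	10	5	0	10	5	0
A02	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0
A03	0	0	20	0	0	20	0	0	20	0	0	20	0	0	20	0	0	20
A04	0	0	0	0	0	0	0	0	0	0	0	7	0	0	0	0	0	0
A05	0	0	15	4	0	0	0	0	9	0	0	0	0	0	0	0	0	0
A06	0	2	6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
A07	0	0	0	0	0	8	5	0	0	0	0	0	0	0	0	0	0	0
A08	0	0	0	6	0	6	0	0	0	0	0	0	0	0	0	0	0	0
A09	12	0	0	0	7	0	0	0	3	0	0	0	0	0	0	0	0	0
A10	9	0	0	0	0	0	0	0	4	0	0	5	0	0	0	0	0	0
A11	20	10	0	15	0	0	0	0	6	0	0	0	0	0	0	0	0	11
A12	8	0	0	8	0	0	8	0	0	8	0	3	8	0	4	8	0	5
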