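# Published category counts for the flight gain/loss enrichment analyses.
# K = genes in category among background, N = background size, n = candidate
# size, O = observed candidates in category. printed_* columns are the values
# as printed in the corresponding result tables (1-decimal display rounding;
# DAVID p-values are EASE-style and treated as approximate cross-checks).
analysis_set	category	method	K	N	n	O	printed_E	printed_FE	printed_p
pterygota_david	Precatalytic spliceosome	ease	34	914	38	7	1.4	5.0	0.00084
pterygota_david	mRNA splicing, via spliceosome	ease	44	914	38	8	1.8	4.4	0.00087
pterygota_david	Catalytic step 2 spliceosome	ease	30	914	38	6	1.2	4.8	0.0032
pterygota_david	Protein binding	ease	81	914	38	8	3.4	2.4	0.035
pterygota_david	Protease	ease	19	914	38	4	0.8	5.1	0.038
pterygota_david	mRNA processing	ease	9	914	38	3	0.4	8.0	0.044
pterygota_panther	RNA catabolic process	binomial	9	894	35	2	0.4	5.7	0.048
flightloss_pos_david	Coiled coil	ease	223	1229	21	9	3.8	2.4	0.018
flightloss_pos_david	Nucleus	ease	269	1229	21	9	4.6	2.0	0.048
flightloss_pos_david	Dendrite morphogenesis	ease	21	1229	21	3	0.4	8.4	0.050
flightloss_pos_panther	Cellular component organization	binomial	113	1207	21	5	2.0	2.5	0.041
flightloss_pos_panther	Organelle organization	binomial	64	1207	21	4	1.1	3.6	0.0229
flightloss_pos_panther	Chromatin organization	binomial	18	1207	21	2	0.3	6.4	0.0387
relaxed_david	mRNA splicing, via spliceosome	ease	50	1231	54	8	2.2	3.6	0.0069
relaxed_david	Catalytic step 2 spliceosome	ease	35	1231	54	6	1.5	3.9	0.021
relaxed_david	Precatalytic spliceosome	ease	39	1231	54	6	1.7	3.5	0.033
relaxed_panther	RNA localization	binomial	11	1209	53	3	0.5	6.2	0.013
relaxed_panther	Death	binomial	13	1209	53	3	0.6	5.3	0.020
relaxed_panther	Cell death	binomial	13	1209	53	3	0.6	5.3	0.020
relaxed_panther	Apoptotic process	binomial	13	1209	53	3	0.6	5.3	0.020
relaxed_panther	Negative regulation of apoptotic process	binomial	1	1209	53	1	0.04	22.8	0.043
relaxed_panther	Localization	binomial	144	1209	53	12	6.3	1.9	0.020
relaxed_panther	Extracellular transport	binomial	1	1209	53	1	0.04	22.8	0.043
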