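phenotype	observed	expected_tetrasomic_1dp	expected_disomic
ab	0	7.5	0
abc	3	45.4	34
abd	45	45.4	34
abcd	77	45.4	68
ac	9	7.5	17
acd	69	45.4	34
ad	26	7.5	17
bc	2	7.5	17
bcd	21	45.4	34
bd	20	7.5	17
cd	0	7.5	0
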