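group	length_cm	span_mb
LG1	75.5	46.9
LG2	71.4	34.3
LG3	75.1	39.1
LG4	86.0	47.5
LG5	87.8	35.3
LG6	99.5	56.5
LG7	80.2	46.3
LG8	77.4	16.1
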