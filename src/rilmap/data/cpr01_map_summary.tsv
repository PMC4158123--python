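group	n_bins	markers_in_bins	singleton_markers	n_markers	length_cm
LG1	18	149	21	170	75.5
LG2	17	87	30	117	71.4
LG3	21	112	20	132	75.1
LG4	30	394	35	429	86.0
LG5	11	38	17	55	87.8
LG6	11	124	32	156	99.5
LG7	24	195	25	220	80.2
LG8	10	30	27	57	77.4
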