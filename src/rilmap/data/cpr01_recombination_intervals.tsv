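chrom	left	right	start_cm	end_cm	span_bp	gc_pct	n_genes	klass
Ca1	scaffold101p2764466	scaffold101p2786728	13.1	14.3	22262	30.2	2	hot
Ca2	CAV1SC817.1P81915	scaffold183p1539190	51.9	53.7	84368	27.5	8	hot
Ca4	CAV1SC25.1P1095606	scaffold1758p2675534	10.2	10.8	27999	31.5	6	hot
Ca4	scaffold1534p1404651	scaffold1534p1421244	73.4	73.9	16593	29.7	2	hot
Ca4	CAV1SC69.1P28720	CAV1SC69.1P34297	74.5	75.1	25188	26.8	2	hot
Ca8	CAV1SC20.1P605299	scaffold928p1221833	36.6	37.9	55103	27.6	6	hot
Ca6	scaffold1441p53604	scaffold213p601853	75.1	75.1	22875656	22.1	906	cold
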