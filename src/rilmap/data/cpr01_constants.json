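{
  "n_lines": 92,
  "generations": 7,
  "mapped_markers": 1336,
  "map_length_cm": 653.0,
  "distorted_markers": 468,
  "total_genes": 28269,
  "population_heterozygosity": 0.064,
  "genome_span_mb": 321.9
}
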