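{
  "D5S818": {
    "name": "D5S818",
    "motif_length": 4,
    "flank_length": 119,
    "gc_fraction": 0.38,
    "forward_primer": "GGGTGATTTTCCTCTTTGGT",
    "reverse_primer": "AACATTTGTATCTTTATCTGTATCCTTATTTAT",
    "allele_range": [7, 16],
    "panel": [[10, 11], [11, 11], [11, 12], [11, 13], [12, 12], [12, 13], [13, 13]],
    "feature_count": 3
  },
  "D18S51": {
    "name": "D18S51",
    "motif_length": 4,
    "flank_length": 131,
    "gc_fraction": 0.40,
    "forward_primer": "CAAACCCGACTACCAGCAAC",
    "reverse_primer": "GAGCCATGTTCATGCCACTG",
    "allele_range": [9, 22],
    "panel": [[12, 14], [12, 15], [12, 16], [13, 14], [13, 16], [14, 15]],
    "feature_count": 4
  }
}
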