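{
  "tool_comparison": [96.45, 95.27, 94.59],
  "panel_exome_duplicates": [96.18, 90.95, 89.14],
  "genome_exome_duplicates": [97.51, 94.64, 93.49]
}
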