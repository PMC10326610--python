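{
 "description": "Summary of the historical fish checklist for the river mainstem (full species list is appendix-only and not reproduced).",
 "summary_counts": {
  "species": 193,
  "genus": 100,
  "family": 20,
  "order": 7
 }
}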