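{
 "informative_pathways": [
  "PW01"
 ],
 "signal_genes": {
  "PW01": {
   "g0001": 1,
   "g0003": -1
  }
 }
}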