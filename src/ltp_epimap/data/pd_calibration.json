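{
  "c": 3.230105838031018,
  "anchor": 13.0,
  "seed": 42,
  "n_pairs": 10000,
  "length": 10,
  "descriptor_table": "atchley_factors.tsv",
  "procedure": "ltp_epimap.pd_index.calibrate: c = anchor / median uncalibrated mean per-position descriptor distance over n_pairs uniformly random unrelated length-10 peptide pairs. Persisted here; never recomputed silently."
}
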