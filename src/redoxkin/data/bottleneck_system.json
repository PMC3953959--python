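{
  "production_rate_M_per_s": 1.2e-2,
  "h2o2_initial_M": 0.0,
  "sinks": [
    {"name": "GPx", "k_M1s1": 6.0e7, "conc_M": 2.0e-6},
    {"name": "GSH", "k_M1s1": 0.87, "conc_M": 5.0e-3}
  ],
  "target": {"name": "PTP1B", "k_M1s1": 20, "total_M": 8.3e-9}
}
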