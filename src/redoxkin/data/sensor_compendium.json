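{
  "version": "1.0",
  "description": "Second-order rate constants for the reaction of H2O2 with thiol and metal sensor proteins. Values in M^-1 s^-1, pH 7.4-7.6 and 37 C unless the temperature note says otherwise.",
  "entries": [
    {
      "name": "GSH",
      "rate_constant": 0.87,
      "category": "thiol-protein",
      "source_note": "literature value for reduced glutathione, pH 7.4",
      "temperature_note": "37 C"
    },
    {
      "name": "Thioredoxin",
      "rate_constant": 1.05,
      "category": "thiol-protein",
      "source_note": "literature value",
      "temperature_note": "37 C"
    },
    {
      "name": "PTP1B",
      "rate_constant": 20,
      "category": "thiol-protein",
      "source_note": "literature value for the recombinant phosphatase",
      "temperature_note": "37 C"
    },
    {
      "name": "KEAP1",
      "rate_constant": 140,
      "category": "thiol-protein",
      "source_note": "estimated in this work from published HeLa dose-response data, corrected for the 6.8 extracellular/intracellular gradient",
      "temperature_note": "cell-based estimate, 37 C"
    },
    {
      "name": "Cdc25B",
      "rate_constant": 160,
      "category": "thiol-protein",
      "source_note": "literature value",
      "temperature_note": "37 C"
    },
    {
      "name": "GAPDH",
      "rate_constant": 500,
      "category": "thiol-protein",
      "source_note": "extrapolated to 37 C from 100 M^-1 s^-1 measured at 0 C",
      "temperature_note": "extrapolated from 0 C"
    },
    {
      "name": "Peroxiredoxin-5",
      "rate_constant": 3.0e5,
      "category": "thiol-protein",
      "source_note": "literature value, human peroxiredoxin 5",
      "temperature_note": "20-25 C"
    },
    {
      "name": "Peroxiredoxin-2",
      "rate_constant": 1.0e7,
      "category": "thiol-protein",
      "source_note": "literature value, human peroxiredoxin 2",
      "temperature_note": "20-25 C"
    },
    {
      "name": "PerR",
      "rate_constant": 1.0e5,
      "category": "metal-protein",
      "source_note": "literature value; sometimes quoted as ~1e5 in running text, stored here at the tabulated 1.0e5",
      "temperature_note": "pH 7"
    },
    {
      "name": "Catalase",
      "rate_constant": 2.0e7,
      "category": "metal-protein",
      "source_note": "literature value for the heme center",
      "temperature_note": "37 C"
    }
  ]
}
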