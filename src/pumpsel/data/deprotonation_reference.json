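{
  "dg_site_deprot": -44.8,
  "dg_bulk_deprot": -51.9,
  "temperature": 303.15,
  "reference_pka": 4.1,
  "expected_delta_pka": 5.1,
  "expected_pka": 9.2,
  "dg_bulk_na_to_k": 18.34
}
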