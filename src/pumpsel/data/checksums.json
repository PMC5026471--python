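{
  "table_ddg_reference.tsv": "7cba23c463008b5eb3bf4af874b9e87684e9045858e5fc1b199a8bf11c8ee8d1",
  "table_boost_reference.tsv": "83ba2438048ff03570f4383e6f2da7167dde0468f3ddaaa9c7cf3d9535a51f3a",
  "deprotonation_reference.json": "fdb717d5246f008b2e84ec98711202bbeabbb9c11936aec5611752ed0f9dcb94"
}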