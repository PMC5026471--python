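# Packaged reference tables

Reference values for the Na⁺/K⁺-pump binding-site selectivity study
conditions that this package re-implements at desk scale.

- `table_ddg_reference.tsv` — reported ΔΔG_Na→K (kcal/mol) with block
  standard errors per binding site (I/II/III) for the wildtype and
  charge-neutralising-mutant scenario roster (E1/E2/P-E2 protonation
  states).  E2/P-E2 systems have two sites; site III columns are empty
  there.
- `table_boost_reference.tsv` — fitted boosting-potential parameters
  k_n (kcal/mol) and χ0_n (degrees) per binding-site residue, 3–6
  cosine terms per row.  The original table prints some cells run
  together; transcription follows a fixed-width rule (k to three
  decimals with trailing zeros sometimes dropped in the printed source,
  phases to one or two decimals).  Empty cells mean the row uses fewer
  terms.
- `deprotonation_reference.json` — the deprotonation worked example:
  site/bulk deprotonation free-energy legs (kcal/mol), the bulk
  aspartate reference pKa, the expected shift, and the reported bulk
  Na→K transformation free energy (18.34 kcal/mol).

`checksums.json` holds SHA-256 digests verified by
`pumpsel.pipeline.load_fixture_tables`.
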