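#!/usr/bin/env python
"""Deprotonation pKa cycle and the reference ΔΔG → K_D-ratio report.

Step 3: (a) runs the toy site-vs-bulk deprotonation cycle for an
acidic ligand surrounded by charged neighbours and reports its pKa
shift; (b) converts every entry of the packaged ΔΔG reference table to
ln(K_D,K/K_D,Na) and K_D ratios, the summary the selectivity figures
are built from.  Writes results/pka_cycle.json and
results/reference_kd_ratios.tsv.
"""

import argparse
import json
import warnings
from pathlib import Path

from pumpsel import load_fixture_tables, pka_from_legs, report_from_table, run_pka_cycle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--profile", default="fast",
                    choices=["tiny", "fast", "paper_analog"])
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    # (a) simulated toy cycle: acidic ligand among charged neighbours
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pk = run_pka_cycle({"n_ligands": 5, "charged": ["L1", "L2", "L3"],
                            "protonated": ["L1"]}, "L1", seed=args.seed,
                           profile=args.profile)
    print(f"toy cycle: ΔG_site = {pk.dg_site:+.1f}, ΔG_bulk = {pk.dg_bulk:+.1f}"
          f" kcal/mol → ΔpKa = {pk.delta_pka:+.1f} "
          f"({'proton retained' if pk.delta_pka > 0 else 'proton released'})")

    # (b) worked example from the packaged deprotonation legs
    deprot = load_fixture_tables().deprotonation
    ref = pka_from_legs(deprot["dg_site_deprot"], deprot["dg_bulk_deprot"],
                        deprot["temperature"],
                        reference_pka=deprot["reference_pka"])
    print(f"reference legs ({ref.dg_site}, {ref.dg_bulk}) kcal/mol → "
          f"ΔpKa = {ref.delta_pka:.2f}, final pKa = {ref.pka:.2f}")

    (RESULTS / "pka_cycle.json").write_text(json.dumps({
        "toy": {"dg_site": pk.dg_site, "dg_bulk": pk.dg_bulk,
                "delta_pka": pk.delta_pka, "pka": pk.pka},
        "reference_worked_example": {
            "dg_site": ref.dg_site, "dg_bulk": ref.dg_bulk,
            "delta_pka": ref.delta_pka, "pka": ref.pka},
        "seed": args.seed}, indent=2, default=float) + "\n")

    report = report_from_table()
    table = report.to_frame()
    table.to_csv(RESULTS / "reference_kd_ratios.tsv", sep="\t", index=False,
                 float_format="%.6g")
    wt = table[(table.scenario == "E1_S1")]
    print("\nreference table, scenario E1_S1 (all sites Na-selective):")
    for _, row in wt.iterrows():
        print(f"  site {row['site']}: ΔΔG = {row.ddg:+.1f} kcal/mol, "
              f"K_D,K/K_D,Na = {row.kd_ratio:,.1f}")
    print(f"wrote {RESULTS/'pka_cycle.json'} and "
          f"{RESULTS/'reference_kd_ratios.tsv'}")


if __name__ == "__main__":
    main()
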