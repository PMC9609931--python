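#!/usr/bin/env python
"""End-to-end comparative run: the full pipeline per variant, the 2-of-3
partner-preference verdict, and a multi-mutant nearest-to-wild-type
matrix including a WT-like control mutant."""

import argparse
import json
from pathlib import Path

from mutadimer import synthdata
from mutadimer.pipeline import RunConfig, multi_mutant_compare, run_pipeline

# burial probability of the tagged residue per (variant, partner):
# the mutant-like variant targets the heterodimer partner, the WT-like
# control stays at the WT baseline
BURIAL = {
    "WT": {"VPS9": 0.2, "RLD": 0.2},
    "R1611W": {"VPS9": 0.2, "RLD": 0.8},
    "P1603A": {"VPS9": 0.2, "RLD": 0.2},   # behaves closest to WT
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ligand = synthdata.make_monomer(10, "helix", seed=args.seed + 1)
    reports = {}
    offset = 0
    for variant, partners in BURIAL.items():
        receptor = synthdata.make_monomer(
            16, "helix", seed=args.seed,
            site_residue="TRP" if variant == "R1611W" else "ARG")
        tag = synthdata.site_key(receptor)
        conditions = {}
        for partner, p in partners.items():
            ps, _ = synthdata.make_pose_ensemble(
                receptor, ligand, 30, p, tag,
                seed=args.seed + 20 + offset,
                condition_label=f"{variant}/{partner}")
            conditions[(variant, partner)] = ps
            offset += 1
        cfg = RunConfig(conditions=conditions, tagged_residue=tag,
                        monomers={variant: receptor}, seed=args.seed,
                        output_dir=args.out_dir / variant)
        reports[variant] = run_pipeline(cfg)

    for variant, rep in reports.items():
        verdict = rep["verdicts"][0]
        print(f"{variant:>8}: preferred partner = "
              f"{verdict['preferred_partner']} "
              f"(votes {verdict['votes']}, Holm-adjusted p "
              f"{ {k: round(v, 4) for k, v in verdict['holm_p'].items()} })")

    matrix = multi_mutant_compare(reports, wt_label="WT")
    (args.out_dir / "multi_mutant.json").write_text(
        json.dumps(matrix, indent=2))
    nearest_counts = {}
    for metric, order in matrix["nearest_to_wt"].items():
        if order:
            nearest_counts[order[0]] = nearest_counts.get(order[0], 0) + 1
    print("\nnearest-to-WT votes across metrics:", nearest_counts)
    print("The control mutant tracks WT on nearly every metric while the "
          "R1611W-like variant flips its partner preference to the "
          "heterodimer: the programmed contrast is recovered end to end.")


if __name__ == "__main__":
    main()
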