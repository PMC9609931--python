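#!/usr/bin/env python
"""Generate the four dimer-pose ensembles (WT / mutant x homodimer-like
VPS9 / heterodimer-like RLD partner) and score the tagged residue:
rank-weighted externalization, per-pose SASA, and the ligand
centre-of-mass contact cloud."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mutadimer import synthdata
from mutadimer.dimers import (
    classify_externalization,
    com_cloud,
    residue_sasa_ensemble,
    two_group_test,
)

BURIAL = {("WT", "VPS9"): 0.2, ("WT", "RLD"): 0.2,
          ("R1611W", "VPS9"): 0.2, ("R1611W", "RLD"): 0.8}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ligand = synthdata.make_monomer(10, "helix", seed=args.seed + 1)
    rows, sasa_rows, clouds = [], [], {}
    ensembles = {}
    for i, ((variant, partner), p) in enumerate(BURIAL.items()):
        receptor = synthdata.make_monomer(
            16, "helix", seed=args.seed,
            site_residue="TRP" if variant == "R1611W" else "ARG")
        tag = synthdata.site_key(receptor)
        ps, _ = synthdata.make_pose_ensemble(
            receptor, ligand, 30, p, tag, seed=args.seed + 10 + i,
            condition_label=f"{variant}/{partner}")
        ensembles[(variant, partner)] = ps
        rep = classify_externalization(ps)
        rows.append({"variant": variant, "partner": partner,
                     "externalization_score": rep.score,
                     **{f"score_fmin_{k}": v
                        for k, v in rep.sensitivity.items()}})
        for v in residue_sasa_ensemble(ps):
            sasa_rows.append({"variant": variant, "partner": partner,
                              "tagged_sasa_A2": v})
        _, _, clusters = com_cloud(ps, grid_spacing=4.0)
        clouds[f"{variant}/{partner}"] = [
            {"members": c["members"], "centroid": c["centroid"].tolist()}
            for c in clusters[:3]]

    scores = pd.DataFrame(rows)
    sasa = pd.DataFrame(sasa_rows)
    scores.to_csv(args.out_dir / "externalization.csv", index=False)
    sasa.to_csv(args.out_dir / "tagged_sasa.csv", index=False)
    (args.out_dir / "contact_clouds.json").write_text(
        json.dumps(clouds, indent=2))

    print(scores.to_string(index=False))
    a = sasa.query("variant=='R1611W' and partner=='RLD'")["tagged_sasa_A2"]
    b = sasa.query("variant=='R1611W' and partner=='VPS9'")["tagged_sasa_A2"]
    t, p = two_group_test(a, b, kind="welch_t")
    print(f"\nMutant tagged-residue SASA, RLD vs VPS9 partner: "
          f"{a.mean():.1f} vs {b.mean():.1f} A^2 (Welch t={t:.2f}, "
          f"p={p:.2e}): the mutant buries its tag preferentially at the "
          "heterodimer interface.")


if __name__ == "__main__":
    main()
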