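#!/usr/bin/env python
"""Steered-unbinding analysis: per-residue RMSD curves and detachment
lags for wild-type-like (early-release) versus mutant-like (late-release)
programmed trajectories, compared by one-way ANOVA."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mutadimer import synthdata
from mutadimer.trajectory import (
    compare_conditions,
    detachment_lag,
    residue_rmsd_series,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    receptor = synthdata.make_monomer(16, "helix", seed=args.seed,
                                      site_residue="TRP")
    ligand = synthdata.make_monomer(10, "helix", seed=args.seed + 1)
    tag = synthdata.site_key(receptor)
    ps, _ = synthdata.make_pose_ensemble(receptor, ligand, 1, 1.0, tag,
                                         seed=args.seed + 5)
    pose = ps.poses[0]
    pulled = [k for k in pose.structure.residue_keys() if k.chain == "B"]

    summaries, lag_rows, curve_frames = {}, [], []
    for variant, start in (("WT", 5), ("R1611W", 30)):
        vals = []
        for rep_i in range(3):
            schedule = {k: min(49, start + 2 * i)
                        for i, k in enumerate(pulled)}
            traj, _ = synthdata.make_trajectory(
                pose, schedule, n_frames=50, dt=0.1, noise_sigma=0.2,
                seed=args.seed + 50 + rep_i)
            series = residue_rmsd_series(traj)
            res = detachment_lag(series, threshold=3.0)
            vals.append(res.summary["all"])
            if rep_i == 0:
                for k, lag in res.per_residue_lag.items():
                    lag_rows.append({"variant": variant, "residue": str(k),
                                     "lag_frame": lag})
                mean_curve = res.group_curves["all"]
                curve_frames.append(pd.DataFrame(
                    {"variant": variant, "frame": mean_curve.index,
                     "mean_rmsd_A": mean_curve.to_numpy()}))
        summaries[variant] = vals

    pd.DataFrame(lag_rows).to_csv(args.out_dir / "detachment_lags.csv",
                                  index=False)
    pd.concat(curve_frames).to_csv(args.out_dir / "rmsd_curves.csv",
                                   index=False)
    ranking, f, p = compare_conditions(summaries)
    pd.DataFrame(ranking).to_csv(args.out_dir / "unbinding_ranking.csv",
                                 index=False)
    for r in ranking:
        print(f"{r['condition']:>8}: mean pulled-domain RMSD "
              f"{r['mean_rmsd']:.2f} A -> {r['label']}")
    print(f"one-way ANOVA: F={f:.1f}, p={p:.2e}")
    print("\nThe mutant-like trajectories lag the RMSD rise: their "
          "residues hold on to the partner surface far longer.")


if __name__ == "__main__":
    main()
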