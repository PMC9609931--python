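"""Steered-unbinding trajectory analytics.

A trajectory is an ordered list of structures with fixed topology plus
pulling metadata (which chain is pulled, which is anchored, distance and
speed).  The analyses mirror how unbinding simulations are read out:
every frame is superposed on frame 0 using the anchored atoms only, each
non-anchored residue's RMSD from its bound position is tracked over time,
and the "detachment lag" of a residue is the first frame at which that
RMSD exceeds a threshold persistently.  Late lags mean the residue clings
to the partner surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimers import two_group_test
from .errors import PDBFormatError
from .structio import ResidueKey, Structure, _kabsch, read_pdb, model_count

ATTACHED = "attached"


@dataclass
class PullingMeta:
    pulled_selection: str = ""       # chain id
    anchored_selection: str = ""     # chain id
    pulling_distance: float = 50.0   # Angstrom
    pulling_speed: float = 10.0      # Angstrom / ns


@dataclass
class Trajectory:
    frames: list[Structure]
    dt: float                        # ns per frame
    pulling: PullingMeta = field(default_factory=PullingMeta)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.frames) < 2:
            raise ValueError("trajectory needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class DetachmentResult:
    per_residue_lag: dict[ResidueKey, object]   # frame index or "attached"
    group_curves: pd.DataFrame                  # frame x group mean RMSD
    summary: dict[str, float]
    threshold: float
    persistence: int


def read_trajectory(path, dt: float,
                    pulling: PullingMeta | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory, verifying fixed topology."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_models = model_count(path)
    if n_models < 2:
        raise PDBFormatError(f"{path}: need >= 2 models, found {n_models}")
    frames = [read_pdb(path, model_index=i) for i in range(n_models)]
    ref = list(zip(frames[0].chain, frames[0].res_id, frames[0].name))
    for f_idx, frame in enumerate(frames[1:], start=1):
        topo = list(zip(frame.chain, frame.res_id, frame.name))
        if topo != ref:
            raise PDBFormatError(
                f"{path}: topology drift at frame {f_idx}")
    return Trajectory(frames, dt, pulling or PullingMeta())


def residue_rmsd_series(t: Trajectory,
                        align_on: str | None = None) -> pd.DataFrame:
    """Per-residue RMSD versus frame 0, after anchored-selection alignment.

    ``align_on`` is the anchored chain id (defaults to the pulling
    metadata).  Returns a DataFrame indexed by frame with one column per
    non-anchored residue (ResidueKey).
    """
    anchor = align_on or t.pulling.anchored_selection
    if not anchor:
        raise ValueError("no anchored selection given")
    f0 = t.frames[0]
    heavy = f0.heavy_mask
    anchor_mask = (f0.chain == anchor) & heavy
    if anchor_mask.sum() < 3:
        raise ValueError(f"anchored chain {anchor!r} has < 3 heavy atoms")
    mobile_mask = (f0.chain != anchor) & heavy
    ref_anchor = f0.coords[anchor_mask]
    ref_mobile = f0.coords[mobile_mask]

    keys = [ResidueKey(c, int(r))
            for c, r in zip(f0.chain[mobile_mask], f0.res_id[mobile_mask])]
    uniq: list[ResidueKey] = []
    for k in keys:
        if not uniq or uniq[-1] != k:
            uniq.append(k)
    key_rows = {k: np.array([i for i, kk in enumerate(keys) if kk == k])
                for k in uniq}

    data = np.zeros((t.n_frames, len(uniq)))
    for fi, frame in enumerate(t.frames):
        R, tr = _kabsch(frame.coords[anchor_mask], ref_anchor)
        moved = frame.coords[mobile_mask] @ R.T + tr
        sq = ((moved - ref_mobile) ** 2).sum(axis=1)
        for ki, k in enumerate(uniq):
            data[fi, ki] = np.sqrt(sq[key_rows[k]].mean())
    return pd.DataFrame(data, columns=uniq,
                        index=pd.RangeIndex(t.n_frames, name="frame"))


def detachment_lag(series: pd.DataFrame, threshold: float = 3.0,
                   persistence: int = 3,
                   groups: dict[str, list[ResidueKey]] | None = None
                   ) -> DetachmentResult:
    """First frame at which each residue's RMSD exceeds ``threshold`` and
    stays above it for ``persistence`` consecutive frames ("attached" if
    never).  Raising the threshold can only delay a lag."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_frames = len(series)
    lags: dict[ResidueKey, object] = {}
    for key in series.columns:
        vals = series[key].to_numpy()
        above = vals > threshold
        lag = ATTACHED
        run = 0
        for f in range(n_frames):
            run = run + 1 if above[f] else 0
            if run >= persistence:
                lag = f - persistence + 1
                break
        lags[key] = lag

    groups = groups or {"all": list(series.columns)}
    curves = pd.DataFrame(
        {name: series[members].mean(axis=1) for name, members in groups.items()})
    summary = {name: float(curves[name].mean()) for name in curves.columns}
    return DetachmentResult(lags, curves, summary, threshold, persistence)


def compare_conditions(results: dict[str, list[float]]):
    """Rank conditions by mean summary RMSD and test the difference.

    Lower mean RMSD of the pulled domain is labelled "stronger residual
    association" (an interpretation label, nothing more).  Returns
    ``(ranking, f_stat, p_value)`` with ranking ordered weakest
    association (highest RMSD) first.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 conditions")
    for label, vals in results.items():
        if len(vals) < 2:
            raise ValueError(f"condition {label!r} needs >= 2 values")
    labels = list(results)
    f, p = two_group_test(*[results[c] for c in labels], kind="anova")
    means = {c: float(np.mean(results[c])) for c in labels}
    order = sorted(labels, key=lambda c: -means[c])
    ranking = [{"condition": c, "mean_rmsd": means[c],
                "label": ("weaker residual association" if i == 0 and len(order) > 1
                          else "stronger residual association"
                          if i == len(order) - 1 else "intermediate")}
               for i, c in enumerate(order)]
    return ranking, f, p
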