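"""Dimer pose-ensemble analytics.

A :class:`PoseSet` is a ranked ensemble of two-chain rigid-body poses of
the same receptor with a docking-engine score per pose (lower = better).
The analytics quantify where the partner lands (contact-density map) and
what happens to one tagged residue: is it left solvent-exposed
("external") or buried at the interface, summarised by a weighted
externalization score in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import sasa as _sasa
from .errors import ManifestError
from .structio import ResidueKey, Structure, read_pdb, superpose

logger = logging.getLogger(__name__)


@dataclass
class DimerPose:
    structure: Structure
    rank: int
    energy_score: float | None = None   # lower = better (ClusPro-style)
    source: str = ""

    def __post_init__(self):
        if len(self.structure.chains) != 2:
            raise ValueError(
                f"pose must have exactly 2 chains, got {self.structure.chains}")


@dataclass
class PoseSet:
    poses: list[DimerPose]
    condition_label: str
    receptor_chain: str
    tagged_residue: ResidueKey
    weighting_fallback: bool = False   # True when energies were absent

    def __post_init__(self):
        ranks = [p.rank for p in self.poses]
        if len(ranks) != len(set(ranks)):
            raise ManifestError("duplicate ranks in pose set")
        self.poses = sorted(self.poses, key=lambda p: p.rank)

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def ligand_chain(self) -> str:
        chains = self.poses[0].structure.chains
        return next(c for c in chains if c != self.receptor_chain)


@dataclass
class ExternalizationReport:
    per_pose: pd.DataFrame      # rank, buried_fraction, external, weight
    score: float
    weighting: str
    f_min: float
    sensitivity: dict[float, float] = field(default_factory=dict)
    excluded_ranks: list[int] = field(default_factory=list)


def load_poseset(directory, manifest, condition_label: str,
                 receptor_chain: str, tagged_residue: ResidueKey) -> PoseSet:
    """Load a pose ensemble from a directory + manifest CSV.

    Manifest columns: ``file``, ``rank`` and optionally ``energy_score``;
    missing energies switch weighting to the rank fallback.
    """
    directory = Path(directory)
    table = pd.read_csv(manifest)
    if "file" not in table.columns or "rank" not in table.columns:
        raise ManifestError("manifest needs 'file' and 'rank' columns")
    if table["rank"].duplicated().any():
        dup = sorted(table.loc[table["rank"].duplicated(), "rank"])
        raise ManifestError(f"duplicate ranks in manifest: {dup}")
    has_energy = "energy_score" in table.columns
    poses = []
    for row in table.itertuples(index=False):
        s = read_pdb(directory / row.file)
        energy = float(row.energy_score) if has_energy else None
        poses.append(DimerPose(s, int(row.rank), energy, source=str(row.file)))
    return PoseSet(poses, condition_label, receptor_chain, tagged_residue,
                   weighting_fallback=not has_energy)


# ---------------------------------------------------------------------------
# Contact-density map
# ---------------------------------------------------------------------------

def com_cloud(ps: PoseSet, grid_spacing: float = 2.0,
              count_threshold: int = 1):
    """Ligand centre-of-mass density in the receptor frame.

    Every pose is superposed on the first pose's receptor chain; ligand
    COMs are binned on a cubic grid.  Returns ``(grid, origin, clusters)``
    where clusters are connected occupied components above the count
    threshold, each with centroid and member count.
    """
    if len(ps) == 0:
        raise ValueError("empty pose set")
    ref = ps.poses[0].structure.select_chains([ps.receptor_chain])
    coms = []
    for pose in ps.poses:
        rec = pose.structure.select_chains([ps.receptor_chain])
        R, t, _ = superpose(rec, ref)
        lig = pose.structure.select_chains([ps.ligand_chain])
        heavy = lig.heavy_mask
        com = lig.coords[heavy].mean(axis=0) @ R.T + t
        coms.append(com)
    coms = np.array(coms)
    origin = coms.min(axis=0) - grid_spacing
    idx = np.floor((coms - origin) / grid_spacing).astype(int)
    shape = idx.max(axis=0) + 2
    grid = np.zeros(shape, dtype=int)
    for i in idx:
        grid[tuple(i)] += 1
    labels, n_lab = ndimage.label(grid >= count_threshold)
    clusters = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        count = int(grid[mask].sum())
        voxels = np.argwhere(mask)
        weights = grid[mask].astype(float)
        centroid = origin + (voxels + 0.5) * grid_spacing
        centroid = (centroid * weights[:, None]).sum(axis=0) / weights.sum()
        clusters.append({"centroid": centroid, "members": count})
    clusters.sort(key=lambda c: -c["members"])
    return grid, origin, clusters


# ---------------------------------------------------------------------------
# Externalization
# ---------------------------------------------------------------------------

def _pose_weights(ps: PoseSet, scheme: str | None, included) -> tuple[np.ndarray, str]:
    energies = [p.energy_score for p in ps.poses]
    if scheme is None:
        scheme = "rank" if any(e is None for e in energies) else "energy"
    if scheme == "energy":
        if any(e is None for e in energies):
            raise ValueError("energy weighting requested but energies missing")
        w = np.array([max(1e-6, -e) for e in energies])
    elif scheme == "rank":
        n = len(ps)
        w = np.array([n - p.rank + 1 for p in ps.poses], dtype=float)
    elif scheme == "uniform":
        w = np.ones(len(ps))
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    w = w * included
    total = w.sum()
    if total <= 0:
        raise ValueError("all poses excluded or zero total weight")
    return w / total, scheme


def pose_buried_fraction(ps: PoseSet, pose: DimerPose,
                         sasa_params=None) -> float:
    """Buried fraction of the tagged residue in one pose (monomer vs dimer)."""
    params = sasa_params or _sasa.SASAParams()
    tag = ps.tagged_residue
    mono = _sasa.residue_sasa(pose.structure, tag, params,
                              chain_subset=[tag.chain])
    in_complex = _sasa.residue_sasa(pose.structure, tag, params)
    if mono <= 0:
        return 0.0
    return float(np.clip((mono - in_complex) / mono, 0.0, 1.0))


def classify_externalization(ps: PoseSet, sasa_params=None,
                             f_min: float = 0.25, weighting: str | None = None,
                             sensitivity=(0.15, 0.25, 0.40)
                             ) -> ExternalizationReport:
    """Weighted externalization score of the tagged residue over an ensemble.

    Each pose contributes a boolean ``external`` (buried fraction of the
    tagged residue below ``f_min``); booleans are combined with
    energy-proportional weights (rank-linear fallback) into a score in
    [0, 1].  Score 1 = the residue always stays solvent-exposed.
    """
    if not 0 < f_min < 1:
        raise ValueError("f_min must be in (0, 1)")
    params = sasa_params or _sasa.SASAParams()
    fractions, included, excluded = [], [], []
    for pose in ps.poses:
        try:
            fractions.append(pose_buried_fraction(ps, pose, params))
            included.append(1.0)
        except Exception as exc:  # pose-level SASA failure: exclude + warn
            logger.warning("pose rank %d excluded: %s", pose.rank, exc)
            fractions.append(np.nan)
            included.append(0.0)
            excluded.append(pose.rank)
    included = np.array(included)
    weights, scheme = _pose_weights(ps, weighting, included)
    fractions = np.array(fractions)
    external = np.where(included > 0, fractions < f_min, False)
    score = float((weights * external).sum())
    sens = {}
    for f in sensitivity:
        ext_f = np.where(included > 0, fractions < f, False)
        sens[f] = float((weights * ext_f).sum())
    per_pose = pd.DataFrame({
        "rank": [p.rank for p in ps.poses],
        "buried_fraction": fractions,
        "external": external,
        "weight": weights,
    })
    return ExternalizationReport(per_pose, score, scheme, f_min, sens,
                                 excluded)


def residue_sasa_ensemble(ps: PoseSet, sasa_params=None) -> list[float]:
    """Tagged-residue SASA (A^2) within each pose complex, in rank order."""
    params = sasa_params or _sasa.SASAParams()
    out = []
    for pose in ps.poses:
        try:
            out.append(_sasa.residue_sasa(pose.structure, ps.tagged_residue,
                                          params))
        except Exception as exc:
            logger.warning("pose rank %d excluded: %s", pose.rank, exc)
    return out


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def two_group_test(a, b=None, *groups, kind: str = "welch_t"):
    """Welch's t-test or one-way ANOVA with degenerate-input conventions.

    ``kind="welch_t"`` compares two samples (unequal variances,
    Welch-Satterthwaite df, two-sided p).  ``kind="anova"`` accepts two or
    more groups.  Zero variance everywhere with equal means returns the
    p = 1 convention instead of NaN.
    """
    if kind == "welch_t":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return np.inf * np.sign(a.mean() - b.mean()), 0.0
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if kind == "anova":
        gs = [np.asarray(g, dtype=float) for g in (a, b, *groups)
              if g is not None]
        if len(gs) < 2 or any(len(g) < 2 for g in gs):
            raise ValueError("anova needs >=2 groups of n >= 2")
        if all(g.std(ddof=1) == 0 for g in gs):
            if len({float(g.mean()) for g in gs}) == 1:
                return 0.0, 1.0
            return np.inf, 0.0
        f, p = stats.f_oneway(*gs)
        return float(f), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
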