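"""Interaction-energy differencing and descriptor-based mutation ddG.

The interaction energy of a rigid dimer pose is
``delta = E(complex) - E(chain A) - E(chain B)`` under a deliberately
simple nonbonded potential: united heavy-atom Lennard-Jones with
Lorentz-Berthelot combining plus Coulomb interactions between coarse
per-residue net charges (Arg/Lys +1, Asp/Glu -1, His +0.1 at the
side-chain centroid) screened by a relative permittivity of 80.  Under
rigidity all intra-chain terms cancel, so delta equals the inter-chain
pair sum; only relative, between-condition comparisons are meaningful.

The mutation ddG is a three-descriptor linear model: volume difference of
the substitution, enthalpy-term difference, and the site's relative SASA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._tables import (
    CANONICAL_RESIDUES,
    GXG_REFERENCE_SASA,
    LJ_DEFAULT,
    LJ_PARAMS,
    RESIDUE_HYDROPATHY,
    RESIDUE_NET_CHARGE,
    RESIDUE_VOLUME,
)
from .dimers import DimerPose, PoseSet, two_group_test
from .errors import AtomTypingError
from .structio import Structure

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 A e^-2


@dataclass(frozen=True)
class NBParams:
    dielectric: float = 80.0
    cutoff: float = 12.0
    lj_params: dict = field(default_factory=lambda: dict(LJ_PARAMS))
    charges: dict = field(default_factory=lambda: dict(RESIDUE_NET_CHARGE))

    def __post_init__(self):
        if self.dielectric < 1:
            raise ValueError("dielectric must be >= 1")
        if any(sig <= 0 for sig, _ in self.lj_params.values()):
            raise ValueError("LJ sigma must be positive")


@dataclass
class InteractionEnergy:
    e_complex: float
    e_a: float
    e_b: float
    delta: float    # e_complex - e_a - e_b (inter-chain sum under rigidity)


def _lj_tables(s: Structure, params: NBParams, strict: bool = False):
    heavy = np.nonzero(s.heavy_mask)[0]
    sigma = np.empty(len(heavy))
    eps = np.empty(len(heavy))
    unknown = []
    for k, i in enumerate(heavy):
        el = s.element[i].upper()
        if el in params.lj_params:
            sigma[k], eps[k] = params.lj_params[el]
        else:
            unknown.append(f"{s.chain[i]}:{s.res_id[i]}:{s.name[i]}({el})")
            sigma[k], eps[k] = LJ_DEFAULT
    if strict and unknown:
        raise AtomTypingError(
            f"{len(unknown)} atoms without LJ parameters", atoms=unknown)
    return heavy, sigma, eps


def _charge_sites(s: Structure, params: NBParams):
    """One point charge per charged residue, at the side-chain centroid
    (CA fallback for truncated side chains)."""
    coords, charges = [], []
    for key in s.residue_keys():
        name = s.residue_name_of(key)
        q = params.charges.get(name)
        if not q:
            continue
        idx = s.atom_indices(key, heavy_only=True)
        side = [i for i in idx if s.name[i] not in ("N", "CA", "C", "O", "OXT")]
        pick = side if side else [i for i in idx if s.name[i] == "CA"] or list(idx)
        coords.append(s.coords[pick].mean(axis=0))
        charges.append(q)
    return np.array(coords).reshape(-1, 3), np.array(charges)


def _system_energy(s: Structure, params: NBParams) -> float:
    """Total nonbonded energy: all heavy-atom LJ pairs + charge-site
    Coulomb pairs within the cutoff (no switching function)."""
    heavy, sigma, eps = _lj_tables(s, params)
    coords = s.coords[heavy]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    energy = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        sig = 0.5 * (sigma[i] + sigma[j])          # Lorentz
        e = np.sqrt(eps[i] * eps[j])               # Berthelot
        sr6 = (sig / r) ** 6
        energy += float((4.0 * e * (sr6 ** 2 - sr6)).sum())
    qc, qv = _charge_sites(s, params)
    if len(qv) > 1:
        qtree = cKDTree(qc)
        qpairs = qtree.query_pairs(r=params.cutoff, output_type="ndarray")
        if len(qpairs):
            i, j = qpairs[:, 0], qpairs[:, 1]
            r = np.linalg.norm(qc[i] - qc[j], axis=1)
            energy += float((COULOMB_CONSTANT * qv[i] * qv[j]
                             / (params.dielectric * r)).sum())
    return energy


def _inter_energy(s: Structure, chain_a: str, chain_b: str,
                  params: NBParams) -> float:
    """Sum of LJ + Coulomb terms between the two chains, within cutoff.

    Individual pair terms are accumulated with an exactly rounded sum
    (math.fsum), so the result is bitwise identical under chain
    relabeling: the pair set and each pair term are symmetric, and the
    summation is order-independent.
    """
    a = s.select_chains([chain_a])
    b = s.select_chains([chain_b])
    ha, sig_a, eps_a = _lj_tables(a, params)
    hb, sig_b, eps_b = _lj_tables(b, params)
    ca, cb = a.coords[ha], b.coords[hb]
    tree = cKDTree(cb)
    terms: list[np.ndarray] = []
    for k in range(len(ca)):
        neigh = tree.query_ball_point(ca[k], r=params.cutoff)
        if not neigh:
            continue
        neigh = np.asarray(neigh)
        r = np.linalg.norm(cb[neigh] - ca[k], axis=1)
        sig = 0.5 * (sig_a[k] + sig_b[neigh])
        e = np.sqrt(eps_a[k] * eps_b[neigh])
        sr6 = (sig / r) ** 6
        terms.append(4.0 * e * (sr6 ** 2 - sr6))
    qca, qva = _charge_sites(a, params)
    qcb, qvb = _charge_sites(b, params)
    if len(qva) and len(qvb):
        d = np.linalg.norm(qca[:, None, :] - qcb[None, :, :], axis=-1)
        within = d <= params.cutoff
        if within.any():
            qq = np.outer(qva, qvb)
            terms.append(COULOMB_CONSTANT * qq[within]
                         / (params.dielectric * d[within]))
    if not terms:
        return 0.0
    return math.fsum(np.concatenate(terms).tolist())


def interaction_energy(pose: DimerPose,
                       params: NBParams | None = None) -> InteractionEnergy:
    """delta = E(complex) - E(A) - E(B) at fixed coordinates.

    With rigid monomers the intra-chain terms of the complex are the
    isolated-chain energies, so the complex energy is assembled as
    intra-A + intra-B + inter and delta is the inter-chain pair sum
    exactly (identically zero once the chains are beyond the cutoff).
    """
    params = params or NBParams()
    s = pose.structure
    chains = s.chains
    if len(chains) != 2:
        raise ValueError("pose must have exactly two chains")
    e_a = _system_energy(s.select_chains([chains[0]]), params)
    e_b = _system_energy(s.select_chains([chains[1]]), params)
    delta = _inter_energy(s, chains[0], chains[1], params)
    return InteractionEnergy(e_a + e_b + delta, e_a, e_b, delta)


# ---------------------------------------------------------------------------
# Descriptor ddG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDGModel:
    """Linear model ddG = c0 + cV*Vdiff + cH*Hdiff + cS*SASA_rel.

    Vdiff (A^3) and Hdiff (model units) are looked up from per-residue
    tables for the wt -> mut substitution; SASA_rel is the site's relative
    solvent accessibility in [0, 1].  Default coefficients are package
    conventions validated for shape only; replace them to calibrate.
    """
    intercept: float = 0.0
    coef_vdiff: float = 0.005
    coef_hdiff: float = 0.8
    coef_sasa: float = 2.0
    volume_table: dict = field(default_factory=lambda: dict(RESIDUE_VOLUME))
    enthalpy_table: dict = field(
        default_factory=lambda: dict(RESIDUE_HYDROPATHY))

    def __post_init__(self):
        for tbl, label in ((self.volume_table, "volume"),
                           (self.enthalpy_table, "enthalpy")):
            missing = [r for r in CANONICAL_RESIDUES if r not in tbl]
            if missing:
                raise ValueError(f"{label} table missing residues {missing}")


def ddg_mutation(sasa_rel: float, wt_residue: str, mut_residue: str,
                 model: DDGModel | None = None) -> float:
    """Descriptor-model ddG (kcal/mol scale) for a point substitution."""
    model = model or DDGModel()
    wt, mut = wt_residue.upper(), mut_residue.upper()
    for r in (wt, mut):
        if r not in model.volume_table or r not in model.enthalpy_table:
            raise ValueError(f"residue {r!r} missing from descriptor tables")
    if not 0.0 <= sasa_rel <= 1.0:
        raise ValueError("sasa_rel must be in [0, 1]")
    vdiff = model.volume_table[mut] - model.volume_table[wt]
    hdiff = model.enthalpy_table[mut] - model.enthalpy_table[wt]
    return (model.intercept + model.coef_vdiff * vdiff
            + model.coef_hdiff * hdiff + model.coef_sasa * sasa_rel)


def relative_sasa(area: float, residue_name: str) -> float:
    """Residue SASA normalised by its Gly-X-Gly reference area, clipped."""
    ref = GXG_REFERENCE_SASA[residue_name.upper()]
    return float(np.clip(area / ref, 0.0, 1.0))


def condition_energy_table(pose_sets: list[PoseSet],
                           params: NBParams | None = None):
    """Per-pose interaction energies across conditions + pairwise tests.

    Returns ``(table, tests, ranking)``: a long-format DataFrame
    (condition, rank, delta), Welch tests per condition pair, and the
    conditions ranked by mean delta (most negative first).
    """
    if len(pose_sets) < 2:
        raise ValueError("need at least two conditions")
    params = params or NBParams()
    rows = []
    for ps in pose_sets:
        for pose in ps.poses:
            ie = interaction_energy(pose, params)
            rows.append({"condition": ps.condition_label, "rank": pose.rank,
                         "delta": ie.delta})
    table = pd.DataFrame(rows)
    labels = [ps.condition_label for ps in pose_sets]
    tests = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = table.loc[table.condition == labels[i], "delta"].to_numpy()
            b = table.loc[table.condition == labels[j], "delta"].to_numpy()
            t, p = two_group_test(a, b, kind="welch_t")
            tests[(labels[i], labels[j])] = {"t": t, "p": p}
    means = table.groupby("condition")["delta"].mean()
    ranking = list(means.sort_values().index)
    return table, tests, ranking
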