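"""Deterministic, seeded generators for every input class.

The analyses in this package were designed against undeposited homology
models and external-engine outputs; these generators stand in with toy
structures that carry *known* statistical structure, so every downstream
statistic has a closed-form or directly simulable expectation:

* ideal-geometry monomers (helix / sheet-slab / bundle) with one taggable
  site residue,
* carved-cavity and convex lattice structures for pocket detection,
* rigid-body dimer-pose ensembles whose tagged-residue burial is a
  Bernoulli draw with a controllable probability per condition,
* unbinding trajectories with a programmed per-residue detachment
  schedule, and
* candidate-compound tables with a planted mutant-specific subset.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimers import DimerPose, PoseSet
from .errors import GenerationError
from .structio import ResidueKey, Structure, concat
from .trajectory import PullingMeta, Trajectory

# backbone ideal geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7

FOLD_ANGLES = {"helix": (-57.0, -47.0), "sheet": (-135.0, 135.0)}


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int
    kind: str          # monomer | cavity | poses | trajectory | candidates
    parameters: dict = field(default_factory=dict)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF atom placement: |cd| = bond, angle(b,c,d) = angle,
    dihedral(a,b,c,d) = torsion."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_segment(n_residues, phi, psi, origin=np.zeros(3)):
    """Backbone N, CA, C, O, CB coordinates for one ideal segment."""
    N = origin + np.array([0.0, 0.0, 0.0])
    CA = origin + np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([math.cos(math.pi - ang),
                                 math.sin(math.pi - ang), 0.0])
    per_res = []
    prevN, prevCA, prevC = N, CA, C
    for i in range(n_residues):
        if i == 0:
            resN, resCA, resC = N, CA, C
        else:
            resN = _place_atom(prevN, prevCA, prevC, _B_C_N, _A_CA_C_N, psi)
            resCA = _place_atom(prevCA, prevC, resN, _B_N_CA, _A_C_N_CA, 180.0)
            resC = _place_atom(prevC, resN, resCA, _B_CA_C, _A_N_CA_C, phi)
        per_res.append((resN, resCA, resC))
        prevN, prevCA, prevC = resN, resCA, resC
    atoms = []
    for i, (resN, resCA, resC) in enumerate(per_res):
        # carbonyl O opposite the next N in the peptide plane
        psi_i = psi if i + 1 < n_residues else 180.0
        O = _place_atom(resN, resCA, resC, _B_C_O, 120.5, psi_i - 180.0)
        CB = _place_atom(resC, resN, resCA, _B_CA_CB, 110.5, 122.6)
        atoms.append({"N": resN, "CA": resCA, "C": resC, "O": O, "CB": CB})
    return atoms


def make_monomer(n_residues: int, fold: str = "helix", seed: int = 0,
                 chain: str = "A", start_resid: int = 1,
                 site_index: int | None = None, site_residue: str = "ARG",
                 sequence_residue: str = "ALA") -> Structure:
    """Ideal-geometry toy monomer with one taggable site residue.

    Poly-alanine by default; the residue at ``site_index`` (0-based along
    the chain, defaults to the middle) gets ``site_residue`` as identity
    so wild-type/mutant runs differ only at the tag.  Supported folds:
    "helix", "sheet-slab" (extended strands laid side by side) and
    "bundle" (two antiparallel helices).
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    if site_index is None:
        site_index = n_residues // 2
    rng = np.random.default_rng(seed)  # reserved for optional jitter; the
    del rng                            # ideal geometry itself is exact

    if fold == "helix":
        segments = [(n_residues, *FOLD_ANGLES["helix"], np.zeros(3))]
    elif fold == "sheet-slab":
        per = 8
        segments = []
        placed = 0
        row = 0
        while placed < n_residues:
            k = min(per, n_residues - placed)
            segments.append((k, *FOLD_ANGLES["sheet"],
                             np.array([0.0, 4.8 * row, 0.0])))
            placed += k
            row += 1
    elif fold == "bundle":
        half = n_residues // 2
        segments = [(half, *FOLD_ANGLES["helix"], np.zeros(3)),
                    (n_residues - half, *FOLD_ANGLES["helix"],
                     np.array([10.0, 0.0, 0.0]))]
    else:
        raise ValueError(f"unsupported fold {fold!r}")

    serial, names, elements, res_names, res_ids, chains, coords = \
        [], [], [], [], [], [], []
    resid = start_resid
    count = 0
    ser = 1
    for seg_i, (k, phi, psi, origin) in enumerate(segments):
        atoms = _build_segment(k, phi, psi, origin)
        if fold == "bundle" and seg_i == 1:  # antiparallel: flip the helix
            for a in atoms:
                for nm in a:
                    a[nm] = np.array([a[nm][0], -a[nm][1],
                                      -a[nm][2]]) + np.array([0.0, 0.0, 10.0])
        for a in atoms:
            res_name = (site_residue if count == site_index
                        else sequence_residue)
            for nm in ("N", "CA", "C", "O", "CB"):
                if nm == "CB" and res_name == "GLY":
                    continue
                serial.append(ser)
                names.append(nm)
                elements.append("N" if nm == "N" else
                                "O" if nm == "O" else "C")
                res_names.append(res_name)
                res_ids.append(resid)
                chains.append(chain)
                coords.append(a[nm])
                ser += 1
            resid += 1
            count += 1
    s = Structure(serial, names, elements, res_names, res_ids, chains,
                  np.array(coords), title=f"synthetic {fold} monomer")
    s.provenance.append(f"make_monomer(n={n_residues}, fold={fold}, "
                        f"seed={seed}, site_index={site_index}, "
                        f"site_residue={site_residue})")
    return s


def site_key(s: Structure) -> ResidueKey:
    """The tagged residue of a generated monomer (the one whose identity
    differs from the poly-X background, else the middle residue)."""
    keys = s.residue_keys()
    names = [s.residue_name_of(k) for k in keys]
    from collections import Counter
    counts = Counter(names)
    background = counts.most_common(1)[0][0]
    for k, n in zip(keys, names):
        if n != background:
            return k
    return keys[len(keys) // 2]


# ---------------------------------------------------------------------------
# Lattice structures for pocket detection
# ---------------------------------------------------------------------------

def _lattice_structure(positions: np.ndarray, chain="A",
                       title="lattice") -> Structure:
    n = len(positions)
    return Structure(np.arange(1, n + 1), ["CA"] * n, ["C"] * n,
                     ["ALA"] * n, np.arange(1, n + 1), [chain] * n,
                     positions, title=title)


def make_carved_slab(seed: int = 0, nx: int = 11, ny: int = 11, nz: int = 5,
                     spacing: float = 2.6, cavity_radius: float = 5.0,
                     jitter: float = 1.0):
    """Solid atom slab with a roughly hemispherical dent carved into its
    top face.  Returns ``(structure, carve_center, target_key)`` where the
    target is the residue at the dent floor."""
    rng = np.random.default_rng(seed)
    xs = spacing * (np.arange(nx) - (nx - 1) / 2)
    ys = spacing * (np.arange(ny) - (ny - 1) / 2)
    zs = spacing * np.arange(nz)
    grid = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    z_top = zs[-1]
    center = np.array([rng.uniform(-jitter, jitter),
                       rng.uniform(-jitter, jitter), z_top])
    keep = np.linalg.norm(grid - center, axis=1) > cavity_radius
    carved = grid[keep]
    s = _lattice_structure(carved, title="synthetic carved slab")
    s.provenance.append(f"make_carved_slab(seed={seed})")
    floor_point = center - np.array([0.0, 0.0, cavity_radius])
    target_i = int(np.argmin(np.linalg.norm(carved - floor_point, axis=1)))
    target = ResidueKey("A", int(s.res_id[target_i]))
    return s, center, target


def make_enclosed_void(seed: int = 0, nx: int = 13, nz: int = 9,
                       spacing: float = 2.6, void_radius: float = 6.5):
    """Solid slab with a fully enclosed spherical void at mid-depth.

    The cleanest cavity-detection fixture: every interior point sees
    protein along all 14 scan directions.  Returns
    ``(structure, void_center, target_key)``."""
    rng = np.random.default_rng(seed)
    xs = spacing * (np.arange(nx) - (nx - 1) / 2)
    zs = spacing * np.arange(nz)
    grid = np.array([(x, y, z) for x in xs for y in xs for z in zs])
    center = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1),
                       zs[nz // 2]])
    keep = np.linalg.norm(grid - center, axis=1) > void_radius
    carved = grid[keep]
    s = _lattice_structure(carved, title="synthetic enclosed void")
    s.provenance.append(f"make_enclosed_void(seed={seed})")
    target_i = int(np.argmin(np.linalg.norm(carved - center, axis=1)))
    target = ResidueKey("A", int(s.res_id[target_i]))
    return s, center, target


def make_convex_ball(seed: int = 0, radius: float = 9.0,
                     spacing: float = 2.6) -> Structure:
    """Solid convex atom ball: must yield no pocket."""
    rng = np.random.default_rng(seed)
    n = int(np.ceil(2 * radius / spacing)) + 1
    ax = spacing * (np.arange(n) - (n - 1) / 2)
    grid = np.array([(x, y, z) for x in ax for y in ax for z in ax])
    shift = rng.uniform(-0.5, 0.5, size=3)
    grid = grid + shift
    keep = np.linalg.norm(grid - shift, axis=1) <= radius
    s = _lattice_structure(grid[keep], title="synthetic convex ball")
    s.provenance.append(f"make_convex_ball(seed={seed})")
    return s


# ---------------------------------------------------------------------------
# Dimer pose ensembles
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


def _approach_contact_t(rec_coords, lig_base, d, contact=4.0):
    """Largest slide parameter t (ligand at lig_base + t*d) at which the
    closest receptor-ligand pair first reaches ``contact`` Angstrom.
    Closed form over all pairs; guarantees min distance == contact."""
    u = rec_coords[:, None, :] - lig_base[None, :, :]
    ud = (u @ d).ravel()
    uu = (u ** 2).sum(axis=-1).ravel()
    disc = ud ** 2 - uu + contact ** 2
    ok = disc >= 0
    if not ok.any():
        return None
    t = ud[ok] + np.sqrt(disc[ok])
    return float(t.max())


def make_pose_ensemble(receptor: Structure, ligand: Structure,
                       n_poses: int = 30, burial_prob: float = 0.5,
                       tagged: ResidueKey | None = None, seed: int = 0,
                       condition_label: str = "synthetic",
                       contact: float = 4.0, max_retries: int = 200):
    """Clash-free rigid-body pose ensemble with programmed tag burial.

    With probability ``burial_prob`` a pose's ligand approaches along the
    outward axis of the tagged residue (burying it at the interface);
    otherwise it approaches a surface patch on the far hemisphere,
    leaving the tag solvent-exposed (no ligand atom within 8 A of it).
    Synthetic energies follow the lower-is-better convention:
    -(heavy-atom contact count) + noise.  Returns ``(pose_set,
    ground_truth)``; the ground truth records the intended burial of each
    rank.
    """
    if not 0.0 <= burial_prob <= 1.0:
        raise ValueError("burial_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    receptor = receptor.with_chain_id("A")
    ligand = ligand.with_chain_id("B")
    if tagged is None:
        tagged = site_key(receptor)
    tagged = ResidueKey("A", tagged.residue_id)

    rec_heavy = receptor.coords[receptor.heavy_mask]
    rec_com = rec_heavy.mean(axis=0)
    tag_idx = receptor.atom_indices(tagged, heavy_only=True)
    cb = [i for i in tag_idx if receptor.name[i] == "CB"]
    tag_point = receptor.coords[cb[0]] if cb else \
        receptor.coords[tag_idx].mean(axis=0)
    u_tag = tag_point - rec_com
    u_tag = u_tag / np.linalg.norm(u_tag)
    lig_centered = ligand.coords - ligand.coords[ligand.heavy_mask].mean(axis=0)
    lig_heavy_mask = ligand.heavy_mask

    records = []
    for pose_i in range(n_poses):
        bury = bool(rng.random() < burial_prob)
        placed = None
        for _ in range(max_retries):
            if bury:
                # small cone around the tag's outward axis
                perturb = rng.normal(scale=0.08, size=3)
                d = u_tag + perturb
                anchor = tag_point
            else:
                d = rng.normal(size=3)
                d = d / np.linalg.norm(d)
                if d @ u_tag > -0.2:   # far hemisphere only
                    continue
                anchor = rec_com
            d = d / np.linalg.norm(d)
            R = _random_rotation(rng)
            lig_rot = lig_centered @ R.T + anchor
            t = _approach_contact_t(rec_heavy, lig_rot[lig_heavy_mask], d,
                                    contact)
            if t is None:
                continue
            lig_coords = lig_rot + t * d
            tag_d = np.linalg.norm(
                lig_coords[lig_heavy_mask][:, None, :]
                - receptor.coords[tag_idx][None, :, :], axis=-1)
            if bury:
                # the tag must carry the contact itself, with enough
                # ligand atoms packed around it to occlude its surface
                if tag_d.min() > contact + 0.3:
                    continue
                if (tag_d.min(axis=1) < 6.0).sum() < 7:
                    continue
            elif tag_d.min() < 8.0:
                continue
            placed = lig_coords
            break
        if placed is None:
            raise GenerationError(
                f"pose placement failed after {max_retries} retries "
                f"(seed={seed}, pose={pose_i}, bury={bury})")
        lig_s = ligand.copy()
        lig_s.coords = placed
        structure = concat(receptor, lig_s)
        dists = np.linalg.norm(
            rec_heavy[:, None, :] - placed[lig_heavy_mask][None, :, :],
            axis=-1)
        contacts = int((dists < 5.0).sum())
        energy = -contacts + rng.normal(0.0, 0.5)
        records.append({"bury": bury, "structure": structure,
                        "energy": energy})

    order = np.argsort([r["energy"] for r in records], kind="stable")
    poses, truth_rows = [], []
    for rank, idx in enumerate(order, start=1):
        rec = records[idx]
        poses.append(DimerPose(rec["structure"], rank, rec["energy"],
                               source=f"synthetic seed={seed}"))
        truth_rows.append({"rank": rank, "intended_buried": rec["bury"]})
    ps = PoseSet(poses, condition_label, receptor_chain="A",
                 tagged_residue=tagged)
    truth = pd.DataFrame(truth_rows)
    return ps, truth


# ---------------------------------------------------------------------------
# Unbinding trajectories
# ---------------------------------------------------------------------------

def make_trajectory(pose: DimerPose,
                    detach_schedule: dict[ResidueKey, int] | None = None,
                    n_frames: int = 50, dt: float = 0.1,
                    noise_sigma: float = 0.0, seed: int = 0,
                    pulling_speed: float = 10.0,
                    pulled_chain: str | None = None):
    """Programmed unbinding trajectory from a dimer pose.

    The pulled chain's residues stay at their bound positions until their
    scheduled frame, then translate along the pulling axis at
    ``pulling_speed`` (A/ns) x ``dt`` per frame; residues with no entry
    never detach.  Gaussian coordinate noise is added to every frame.
    Returns ``(trajectory, ground_truth)`` with the schedule echoed as
    ground truth.
    """
    detach_schedule = detach_schedule or {}
    rng = np.random.default_rng(seed)
    s0 = pose.structure
    chains = s0.chains
    pulled = pulled_chain or chains[-1]
    anchored = next(c for c in chains if c != pulled)
    if any(f >= n_frames or f < 0 for f in detach_schedule.values()):
        raise ValueError("schedule frames must lie in [0, n_frames)")

    anchor_com = s0.select_chains([anchored]).coords.mean(axis=0)
    pulled_com = s0.select_chains([pulled]).coords.mean(axis=0)
    axis = pulled_com - anchor_com
    axis = axis / np.linalg.norm(axis)
    step = pulling_speed * dt

    frames = []
    for f in range(n_frames):
        coords = s0.coords.copy()
        for key, start in detach_schedule.items():
            if f > start:
                idx = s0.atom_indices(key)
                coords[idx] += axis * step * (f - start)
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
        frame = s0.copy()
        frame.coords = coords
        frames.append(frame)
    meta = PullingMeta(pulled_selection=pulled, anchored_selection=anchored,
                       pulling_distance=step * (n_frames - 1),
                       pulling_speed=pulling_speed)
    traj = Trajectory(frames, dt, meta)
    truth = {k: int(v) for k, v in detach_schedule.items()}
    return traj, truth


def expected_lag(schedule_frame: int, threshold: float, dt: float,
                 pulling_speed: float) -> int:
    """Closed-form noiseless lag: ceil(schedule + threshold/(v*dt)).

    When threshold is an exact multiple of the per-frame step the
    crossing is a tie; the ceil convention counts it as crossed, which
    matches the floating-point accumulation of the generator, but exact
    assertions should use non-commensurate thresholds.
    """
    step = pulling_speed * dt
    return schedule_frame + int(math.ceil(threshold / step - 1e-9))


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

DEFAULT_DESCRIPTOR_DISTRIBUTIONS = {
    "lgBB": (-0.5, 0.8),
    "SOLY": (0.0, 1.0),
    "logP_oct": (2.0, 1.5),
    "logP_chex": (1.5, 1.5),
}


def make_candidates(n: int, descriptor_distributions: dict | None = None,
                    fraction_specific: float = 0.1, effect_size: float = 5.0,
                    seed: int = 0, orientation: str = "affinity",
                    pair_noise_sd: float = 0.3):
    """Candidate table with a planted mutant-specific subset.

    Descriptors are drawn from per-column normal distributions; every
    candidate gets paired docking scores whose difference is pure noise
    (sd ``pair_noise_sd``) except for a ``fraction_specific`` subset whose
    mutant score is advantaged by ``effect_size`` noise-sd units.
    Returns ``(table, specific_ids)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = descriptor_distributions or DEFAULT_DESCRIPTOR_DISTRIBUTIONS
    rng = np.random.default_rng(seed)
    ids = [f"CMPD{i:05d}" for i in range(n)]
    table = pd.DataFrame({"id": ids})
    for name, (mu, sd) in dists.items():
        table[name] = rng.normal(mu, sd, size=n)
    base = rng.normal(-7.0, 1.0, size=n)
    noise = rng.normal(0.0, pair_noise_sd, size=n)
    n_specific = int(round(fraction_specific * n))
    specific_idx = rng.choice(n, size=n_specific, replace=False)
    advantage = np.zeros(n)
    shift = effect_size * pair_noise_sd
    advantage[specific_idx] = -shift if orientation == "affinity" else shift
    table["score_wt"] = base
    table["score_mut"] = base + noise + advantage
    specific_ids = sorted(ids[i] for i in specific_idx)
    return table, specific_ids
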