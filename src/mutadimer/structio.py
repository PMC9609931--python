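"""Structure data model, PDB I/O and geometry primitives.

The :class:`Structure` container stores atoms as parallel numpy arrays
(coordinates in Angstrom, author residue numbering, per-atom van der Waals
radii assigned from the built-in NACCESS-compatible table).  All geometric
analyses in this package operate on heavy atoms; hydrogens are carried
through I/O but excluded from distances, surfaces and energies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from ._tables import (
    CANONICAL_RESIDUES,
    DEFAULT_VDW,
    RAMACHANDRAN_BOXES,
    VDW_RADII,
)
from .errors import DegenerateGeometryError, PairingError, PDBFormatError

logger = logging.getLogger(__name__)

#: atom names retained when a residue's identity is substituted in silico
_SUBSTITUTION_KEEP = {"N", "CA", "C", "O", "OXT", "CB"}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identifies one residue by chain id and author residue number."""

    chain: str
    residue_id: int

    def __str__(self) -> str:  # "A:1611" selection syntax
        return f"{self.chain}:{self.residue_id}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        chain, resid = text.split(":")[:2]
        return cls(chain, int(resid))


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    coords: np.ndarray
    occupancy: float
    bfactor: float
    vdw_radius: float


def _vdw_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


class Structure:
    """Ordered atom collection with array-backed fields."""

    def __init__(self, serial, name, element, res_name, res_id, chain,
                 coords, occupancy=None, bfactor=None, title="",
                 provenance=None):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.res_name = np.asarray(res_name, dtype=object)
        self.res_id = np.asarray(res_id, dtype=np.int64)
        self.chain = np.asarray(chain, dtype=object)
        self.coords = np.array(coords, dtype=float).reshape(n, 3)
        self.occupancy = (np.ones(n) if occupancy is None
                          else np.asarray(occupancy, dtype=float))
        self.bfactor = (np.zeros(n) if bfactor is None
                        else np.asarray(bfactor, dtype=float))
        self.vdw = np.array([_vdw_for(e) for e in self.element], dtype=float)
        self.title = title
        self.provenance: list[str] = list(provenance or [])
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return list(seen)

    def atom(self, i: int) -> Atom:
        return Atom(int(self.serial[i]), self.name[i], self.element[i],
                    self.res_name[i], int(self.res_id[i]), self.chain[i],
                    self.coords[i].copy(), float(self.occupancy[i]),
                    float(self.bfactor[i]), float(self.vdw[i]))

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.element])

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for c, r in zip(self.chain, self.res_id):
            seen.setdefault(ResidueKey(c, int(r)))
        return list(seen)

    def atom_indices(self, key: ResidueKey, heavy_only: bool = False):
        mask = (self.chain == key.chain) & (self.res_id == key.residue_id)
        if heavy_only:
            mask &= self.heavy_mask
        return np.nonzero(mask)[0]

    def resolve(self, key: ResidueKey) -> np.ndarray:
        idx = self.atom_indices(key)
        if len(idx) == 0:
            raise KeyError(f"residue {key} not present in structure")
        return idx

    def residue_name_of(self, key: ResidueKey) -> str:
        return self.res_name[self.resolve(key)[0]]

    # -- derived structures ---------------------------------------------
    def _subset(self, idx) -> "Structure":
        return Structure(self.serial[idx], self.name[idx], self.element[idx],
                         self.res_name[idx], self.res_id[idx],
                         self.chain[idx], self.coords[idx],
                         self.occupancy[idx], self.bfactor[idx],
                         title=self.title, provenance=self.provenance)

    def select_chains(self, chains) -> "Structure":
        chains = set(chains)
        idx = np.array([c in chains for c in self.chain])
        if not idx.any():
            raise ValueError(f"no atoms in chains {sorted(chains)}")
        return self._subset(idx)

    def copy(self) -> "Structure":
        return self._subset(np.arange(self.n_atoms))

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + translation
        return out

    def with_chain_id(self, new_chain: str) -> "Structure":
        out = self.copy()
        out.chain = np.array([new_chain] * self.n_atoms, dtype=object)
        return out

    def validate(self) -> None:
        keys = list(zip(self.chain, self.res_id, self.name))
        if len(keys) != len(set(keys)):
            raise ValueError("(chain, residue_id, name) not unique")
        for key in self.residue_keys():
            if not self.heavy_mask[self.atom_indices(key)].any():
                raise ValueError(f"residue {key} has no heavy atom")


def concat(a: Structure, b: Structure) -> Structure:
    """Merge two structures (e.g. receptor + ligand chains) into one."""
    return Structure(
        np.concatenate([a.serial, b.serial + a.serial.max() + 1]),
        np.concatenate([a.name, b.name]),
        np.concatenate([a.element, b.element]),
        np.concatenate([a.res_name, b.res_name]),
        np.concatenate([a.res_id, b.res_id]),
        np.concatenate([a.chain, b.chain]),
        np.vstack([a.coords, b.coords]),
        np.concatenate([a.occupancy, b.occupancy]),
        np.concatenate([a.bfactor, b.bfactor]),
        title=a.title, provenance=a.provenance + b.provenance)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _prevalidate_pdb_text(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise PDBFormatError(
                    f"{path}: truncated ATOM record at line {lineno}")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(stripped[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"{path}: unparsable coordinates at line {lineno}") from None


def _structure_from_atom_array(arr: bst.AtomArray, title="") -> Structure:
    element = [e if e else n.strip("0123456789")[:1]
               for e, n in zip(arr.element, arr.atom_name)]
    occupancy = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
                 else None)
    bfactor = (arr.b_factor if "b_factor" in arr.get_annotation_categories()
               else None)
    return Structure(np.arange(1, arr.array_length() + 1), arr.atom_name,
                     element, arr.res_name, arr.res_id, arr.chain_id,
                     arr.coord, occupancy, bfactor, title=title)


def read_pdb(path, model_index: int | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model_index`` is zero-based; ``None`` selects the first model.
    """
    _prevalidate_pdb_text(path)
    try:
        pdbf = PDBFile.read(str(path))
        n_models = pdbf.get_model_count()
    except Exception as exc:  # biotite-level parse failure
        raise PDBFormatError(f"{path}: {exc}") from exc
    if model_index is None:
        model_index = 0
    if not 0 <= model_index < n_models:
        raise IndexError(
            f"model_index {model_index} out of range ({n_models} models)")
    arr = pdbf.get_structure(model=model_index + 1,
                             extra_fields=["occupancy", "b_factor"])
    return _structure_from_atom_array(arr, title=str(path))


def model_count(path) -> int:
    return PDBFile.read(str(path)).get_model_count()


def _to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = np.asarray(s.chain, dtype="U4")
    arr.res_id = s.res_id.astype(int)
    arr.res_name = np.asarray(s.res_name, dtype="U5")
    arr.atom_name = np.asarray(s.name, dtype="U6")
    arr.element = np.asarray([e.upper() for e in s.element], dtype="U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.set_annotation("occupancy", s.occupancy.astype(np.float32))
    arr.set_annotation("b_factor", s.bfactor.astype(np.float32))
    return arr


def write_pdb(s: Structure | list[Structure], path) -> None:
    """Write a structure (or a list of models) as PDB."""
    pdbf = PDBFile()
    if isinstance(s, Structure):
        pdbf.set_structure(_to_atom_array(s))
    else:
        stack = bst.stack([_to_atom_array(m) for m in s])
        pdbf.set_structure(stack)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def neighbors_within(s: Structure, center: ResidueKey,
                     radius: float) -> list[ResidueKey]:
    """Residues with any heavy atom within ``radius`` of the center residue.

    The center residue is always included.  Results are sorted by
    (chain, residue_id).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center_idx = s.resolve(center)
    center_idx = center_idx[s.heavy_mask[center_idx]]
    heavy = np.nonzero(s.heavy_mask)[0]
    tree = cKDTree(s.coords[heavy])
    hits: set[int] = set()
    for lst in tree.query_ball_point(s.coords[center_idx], r=radius):
        hits.update(lst)
    keys = {ResidueKey(s.chain[heavy[i]], int(s.res_id[heavy[i]]))
            for i in hits}
    keys.add(center)
    return sorted(keys, key=lambda k: (k.chain, k.residue_id))


def _paired_coords(mobile: Structure, reference: Structure,
                   selection=None):
    """Match heavy atoms 1:1 by (chain, residue_id, atom name)."""
    sel = None if selection is None else set(selection)

    def keyed(st):
        out = {}
        for i in range(st.n_atoms):
            if st.element[i].upper() == "H":
                continue
            if sel is not None and st.name[i] not in sel:
                continue
            out[(st.chain[i], int(st.res_id[i]), st.name[i])] = i
        return out

    km, kr = keyed(mobile), keyed(reference)
    common = [k for k in km if k in kr]
    if len(common) < 3:
        raise PairingError(
            f"only {len(common)} matched atoms; need at least 3")
    mi = np.array([km[k] for k in common])
    ri = np.array([kr[k] for k in common])
    return mobile.coords[mi], reference.coords[ri], common


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rotation R, translation t with R@p + t ~= q."""
    cm_p, cm_q = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cm_p, Q - cm_q
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise DegenerateGeometryError("selection is (near-)collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cm_q - R @ cm_p
    return R, t


def superpose(mobile: Structure, reference: Structure, selection=None):
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where the transform maps
    mobile coordinates onto the reference frame and rmsd is evaluated over
    the matched selection.
    """
    P, Q, _ = _paired_coords(mobile, reference, selection)
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def per_residue_rmsd(mobile: Structure,
                     reference: Structure) -> dict[ResidueKey, float]:
    """Per-residue heavy-atom RMSD after one global superposition."""
    P, Q, keys = _paired_coords(mobile, reference, None)
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    sq = ((moved - Q) ** 2).sum(axis=1)
    acc: dict[ResidueKey, list[float]] = {}
    for (chain, resid, _), d2 in zip(keys, sq):
        acc.setdefault(ResidueKey(chain, resid), []).append(d2)
    return {k: float(math.sqrt(np.mean(v))) for k, v in acc.items()}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = -(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def _in_boxes(phi, psi, boxes) -> bool:
    return any(lo_f <= phi <= hi_f and lo_s <= psi <= hi_s
               for lo_f, hi_f, lo_s, hi_s in boxes)


def ramachandran(s: Structure, boxes=None, peptide_bond_max=2.5):
    """Backbone dihedrals and coarse allowed-region classification.

    Returns ``(records, n_violations)`` where records is a list of dicts
    with chain, residue_id, residue_name, phi, psi, defined, allowed.
    Terminal residues and chain breaks are flagged undefined.
    """
    boxes = boxes or RAMACHANDRAN_BOXES
    records = []
    n_violations = 0
    for chain in s.chains:
        resids = []
        for c, r in zip(s.chain, s.res_id):
            if c == chain and (not resids or resids[-1] != int(r)):
                resids.append(int(r))
        bb = {}
        for r in resids:
            idx = s.atom_indices(ResidueKey(chain, r))
            names = {s.name[i]: s.coords[i] for i in idx}
            bb[r] = names
        for j, r in enumerate(resids):
            names = bb[r]
            phi = psi = None
            have_bb = all(a in names for a in ("N", "CA", "C"))
            if not have_bb:
                logger.warning("residue %s:%d missing backbone atoms",
                               chain, r)
            if have_bb and j > 0:
                prev = bb[resids[j - 1]]
                if "C" in prev and np.linalg.norm(
                        prev["C"] - names["N"]) <= peptide_bond_max:
                    phi = dihedral(prev["C"], names["N"], names["CA"],
                                   names["C"])
            if have_bb and j < len(resids) - 1:
                nxt = bb[resids[j + 1]]
                if "N" in nxt and np.linalg.norm(
                        names["C"] - nxt["N"]) <= peptide_bond_max:
                    psi = dihedral(names["N"], names["CA"], names["C"],
                                   nxt["N"])
            defined = phi is not None and psi is not None
            res_name = s.res_name[s.atom_indices(ResidueKey(chain, r))[0]]
            allowed = None
            if defined:
                cls = res_name if res_name in ("GLY", "PRO") else "general"
                allowed = _in_boxes(phi, psi, boxes[cls])
                if not allowed:
                    n_violations += 1
            records.append({"chain": chain, "residue_id": r,
                            "residue_name": res_name, "phi": phi, "psi": psi,
                            "defined": defined, "allowed": allowed})
    return records, n_violations


def substitute_residue(s: Structure, site: ResidueKey,
                       new_residue: str) -> Structure:
    """Identity-level residue substitution.

    Replaces the residue name at ``site`` and truncates the side chain
    beyond CB (no rotamer rebuilding); downstream descriptor analyses use
    the new identity.  A provenance note is recorded on the result.
    """
    new_residue = new_residue.upper()
    if new_residue not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue code {new_residue!r}")
    idx = s.resolve(site)
    old = s.res_name[idx[0]]
    keep = np.ones(s.n_atoms, dtype=bool)
    in_site = np.zeros(s.n_atoms, dtype=bool)
    in_site[idx] = True
    for i in idx:
        if s.name[i] not in _SUBSTITUTION_KEEP:
            keep[i] = False
    if new_residue == "GLY":
        for i in idx:
            if s.name[i] == "CB":
                keep[i] = False
    out = s._subset(np.nonzero(keep)[0])
    out.res_name = out.res_name.copy()
    out.res_name[(out.chain == site.chain)
                 & (out.res_id == site.residue_id)] = new_residue
    out.provenance = s.provenance + [
        f"substituted {old}->{new_residue} at {site} (side chain truncated)"]
    return out
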