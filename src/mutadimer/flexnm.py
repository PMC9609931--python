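"""Elastic-network-model flexibility profiles (GNM / ANM).

Coarse-grained CA-node networks with a distance cutoff; per-residue
fluctuation (RMSF, arbitrary units) from the pseudo-inverse of the
Kirchhoff (GNM) or Hessian (ANM) matrix.  Used comparatively: wild-type
versus mutant profiles, where the mutation enters as a local
contact-weight change rather than a rebuilt structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from ._tables import SIDECHAIN_HEAVY_ATOMS
from .errors import ConnectivityError, PairingError
from .structio import ResidueKey, Structure

_ZERO_TOL_GNM = 1e-10


@dataclass
class ENMModel:
    kind: str                    # "gnm" | "anm"
    cutoff: float
    gamma: float
    nodes: np.ndarray            # (n, 3) CA coordinates
    keys: list[ResidueKey]
    matrix: np.ndarray           # Kirchhoff (n,n) or Hessian (3n,3n)
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def n_zero_modes(self) -> int:
        scale = max(self.eigvals.max(), 1.0)
        tol = _ZERO_TOL_GNM * scale if self.kind == "gnm" else 1e-8 * scale
        return int((self.eigvals < tol).sum())


@dataclass
class FlexProfile:
    rmsf: dict[ResidueKey, float]
    normalized: bool = False

    def values(self) -> np.ndarray:
        return np.array(list(self.rmsf.values()))


def _ca_nodes(s: Structure):
    keys, coords, names = [], [], []
    for i in range(s.n_atoms):
        if s.name[i] == "CA":
            keys.append(ResidueKey(s.chain[i], int(s.res_id[i])))
            coords.append(s.coords[i])
            names.append(s.res_name[i])
    return keys, np.array(coords), names


def kirchhoff_matrix(coords: np.ndarray, cutoff: float,
                     gamma: float = 1.0) -> np.ndarray:
    """GNM Kirchhoff (connectivity) matrix for a set of nodes: off-diagonal
    -gamma for pairs within the cutoff, diagonal = contact count * gamma."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    k = -gamma * adj.astype(float)
    np.fill_diagonal(k, gamma * adj.sum(axis=1))
    return k


def build_enm(s: Structure, kind: str = "gnm", cutoff: float | None = None,
              gamma: float = 1.0, contact_weighting: str = "uniform",
              weight_site: ResidueKey | None = None) -> ENMModel:
    """Build a GNM or ANM from the CA trace of ``s``.

    ``contact_weighting="sidechain"`` scales each spring by the geometric
    mean of the side-chain heavy-atom counts of its endpoints — the
    identity-level proxy by which a residue substitution (heavier or
    lighter side chain) perturbs local packing without rebuilding
    coordinates.
    """
    kind = kind.lower()
    if kind not in ("gnm", "anm"):
        raise ValueError(f"unknown ENM kind {kind!r}")
    if cutoff is None:
        cutoff = 10.0 if kind == "gnm" else 15.0
    keys, coords, res_names = _ca_nodes(s)
    n = len(keys)
    if n < 10:
        raise ValueError(f"need at least 10 CA atoms, found {n}")

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)

    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [[str(k) for k, l in zip(keys, labels) if l == c]
                 for c in range(n_comp)]
        raise ConnectivityError(
            f"network disconnected at cutoff {cutoff} A "
            f"({n_comp} components); increase the cutoff", components=comps)

    if contact_weighting == "uniform":
        w_node = np.ones(n)
    elif contact_weighting == "sidechain":
        w_node = np.array([max(SIDECHAIN_HEAVY_ATOMS.get(r, 1), 1) / 4.0
                           for r in res_names])
    else:
        raise ValueError(f"unknown contact_weighting {contact_weighting!r}")
    spring = gamma * np.sqrt(np.outer(w_node, w_node)) * adj

    if kind == "gnm":
        kirchhoff = -spring
        np.fill_diagonal(kirchhoff, spring.sum(axis=1))
        eigvals, eigvecs = np.linalg.eigh(kirchhoff)
        matrix = kirchhoff
    else:
        hessian = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for j in range(n):
                if not adj[i, j]:
                    continue
                dij = diff[i, j]
                block = -spring[i, j] * np.outer(dij, dij) / (dist[i, j] ** 2)
                hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
                hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        eigvals, eigvecs = np.linalg.eigh(hessian)
        matrix = hessian
    eigvals = np.maximum(eigvals, 0.0)
    return ENMModel(kind, cutoff, gamma, coords, keys, matrix,
                    eigvals, eigvecs)


def rmsf_profile(m: ENMModel) -> FlexProfile:
    """Per-residue fluctuation from the non-zero modes.

    GNM: diagonal of the Kirchhoff pseudo-inverse; ANM: trace of the 3x3
    diagonal blocks of the Hessian pseudo-inverse.  Arbitrary units.
    """
    nz = m.n_zero_modes
    lam = m.eigvals[nz:]
    vec = m.eigvecs[:, nz:]
    diag = (vec ** 2 / lam).sum(axis=1)
    if m.kind == "anm":
        diag = diag.reshape(-1, 3).sum(axis=1)
    return FlexProfile({k: float(v) for k, v in zip(m.keys, diag)})


def normalize_profile(p: FlexProfile) -> FlexProfile:
    med = float(np.median(p.values()))
    if med <= 0:
        raise ValueError("non-positive median fluctuation")
    return FlexProfile({k: v / med for k, v in p.rmsf.items()},
                       normalized=True)


def compare_profiles(wt: FlexProfile, mut: FlexProfile,
                     z_threshold: float = 2.0):
    """Per-residue fluctuation difference after median normalisation.

    Returns ``(delta, flagged)``: delta maps common residues to
    mut - wt (negative = mutant more rigid there); flagged lists residues
    whose |delta| exceeds ``z_threshold`` robust standard deviations.
    """
    common = [k for k in wt.rmsf if k in mut.rmsf]
    if not common:
        raise PairingError("profiles share no residues")
    w = normalize_profile(FlexProfile({k: wt.rmsf[k] for k in common}))
    m = normalize_profile(FlexProfile({k: mut.rmsf[k] for k in common}))
    delta = {k: m.rmsf[k] - w.rmsf[k] for k in common}
    vals = np.array(list(delta.values()))
    mad = np.median(np.abs(vals - np.median(vals)))
    scale = 1.4826 * mad if mad > 0 else (vals.std() if vals.std() > 0 else 1.0)
    flagged = [k for k, v in delta.items() if abs(v) > z_threshold * scale]
    return delta, flagged
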