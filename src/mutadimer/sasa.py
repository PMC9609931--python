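"""Shrake-Rupley solvent-accessible surface area.

Per-atom SASA is the accessible fraction of a sphere of radius
``r_vdw + probe`` estimated on a deterministic quasi-uniform Fibonacci
lattice, with occlusion tested against all neighbouring heavy atoms.  The
lattice is expressed in the molecule's principal-axis frame so that the
result is (to lattice resolution) invariant under rigid transforms of the
input — no random numbers are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError
from .structio import ResidueKey, Structure


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radius_set: str = "naccess"

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 100:
            raise ValueError("n_points must be at least 100")


@dataclass
class SASAResult:
    per_atom: dict[int, float]          # atom serial -> Angstrom^2
    per_residue: dict[ResidueKey, float]
    total: float
    params: SASAParams = field(default_factory=SASAParams)

    def residue_area(self, key: ResidueKey) -> float:
        return self.per_residue[key]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-equivariant orthonormal frame from the coordinate cloud.

    Eigenvectors of the covariance, signs fixed by the third central moment
    along each axis so the frame co-rotates with the molecule.
    """
    if len(coords) < 3:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(2):
        proj = centered @ vecs[:, k]
        skew = (proj ** 3).sum()
        if abs(skew) > 1e-9:
            if skew < 0:
                vecs[:, k] = -vecs[:, k]
        elif vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return vecs


def compute_sasa(s: Structure, params: SASAParams | None = None,
                 chain_subset=None, atom_subset=None) -> SASAResult:
    """Shrake-Rupley SASA of the heavy atoms of ``s``.

    ``chain_subset`` restricts both the reported atoms and the occluders
    (the selection is treated as an isolated molecule).  ``atom_subset``
    (indices into ``s``) restricts only which atoms' areas are computed;
    occlusion still uses the full selection — this is the fast path for
    single-residue queries over pose ensembles.
    """
    params = params or SASAParams()
    sel = s if chain_subset is None else s.select_chains(chain_subset)
    heavy = np.nonzero(sel.heavy_mask)[0]
    if len(heavy) == 0:
        raise ValueError("no heavy atoms in selection")
    coords = sel.coords[heavy]
    radii = sel.vdw[heavy] + params.probe_radius

    frame = _principal_frame(coords)
    lattice = fibonacci_sphere(params.n_points) @ frame.T

    if atom_subset is None:
        targets = np.arange(len(heavy))
    else:
        wanted = set(int(i) for i in np.atleast_1d(atom_subset))
        targets = np.array([k for k, i in enumerate(heavy) if i in wanted],
                           dtype=int)
        if len(targets) == 0:
            raise ValueError("atom_subset selects no heavy atoms")

    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom: dict[int, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for k in targets:
        i = heavy[k]
        neigh = tree.query_ball_point(coords[k], r=radii[k] + max_r)
        neigh = [j for j in neigh if j != k
                 and np.linalg.norm(coords[j] - coords[k]) < radii[k] + radii[j]]
        pts = coords[k] + radii[k] * lattice
        accessible = np.ones(params.n_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radii[k] ** 2 * accessible.mean()
        per_atom[int(sel.serial[i])] = float(area)
        key = ResidueKey(sel.chain[i], int(sel.res_id[i]))
        per_residue[key] = per_residue.get(key, 0.0) + float(area)

    total = float(sum(per_atom.values()))
    return SASAResult(per_atom, per_residue, total, params)


def residue_sasa(s: Structure, key: ResidueKey,
                 params: SASAParams | None = None,
                 chain_subset=None) -> float:
    """SASA (Angstrom^2) of one residue within ``s`` (fast path)."""
    sel = s if chain_subset is None else s.select_chains(chain_subset)
    idx = sel.resolve(key)
    res = compute_sasa(sel, params, atom_subset=idx)
    return res.per_residue[key]


def burial(mono: SASAResult, complexed: SASAResult, site: ResidueKey):
    """Buried area and buried fraction of ``site`` upon complexation.

    ``delta_sasa = SASA_mono - SASA_complex`` (small negatives from lattice
    re-orientation are clipped to zero); ``fraction`` is delta over the
    monomer area, 0 when the residue is already fully buried in the monomer.
    """
    if mono.params != complexed.params:
        raise ConsistencyError(
            f"SASA params differ: {mono.params} vs {complexed.params}")
    if site not in mono.per_residue or site not in complexed.per_residue:
        raise KeyError(f"residue {site} missing from SASA result")
    a_mono = mono.per_residue[site]
    delta = a_mono - complexed.per_residue[site]
    if delta < -1e-6 * max(1.0, a_mono):
        delta = max(delta, 0.0)  # lattice noise only; never meaningful
    delta = max(delta, 0.0)
    fraction = 0.0 if a_mono <= 0 else min(1.0, delta / a_mono)
    return delta, fraction
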