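"""Binding-pocket definition around a target residue.

Two stages, mirroring the screening workflow: (1) the shell of residues
with heavy atoms within a radius of the target (default 5 A); (2)
grid-based cavity detection of the LIGSITE family — voxels outside all
probe-inflated atom spheres count as cavity when enough of 14 scan
directions (6 axial + 8 diagonal) hit protein, i.e. the empty space is
enclosed rather than open solvent.  The cavity cluster nearest the target
is reported with volume, centroid and a docking box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import structio
from .structio import ResidueKey, Structure

_AXIAL = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_DIAGONAL = [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
SCAN_DIRECTIONS = _AXIAL + _DIAGONAL   # 14 rays


@dataclass
class PocketReport:
    shell_residues: list[ResidueKey]
    pocket_found: bool
    lining_residues: list[ResidueKey] = field(default_factory=list)
    volume: float = 0.0                     # Angstrom^3
    centroid: np.ndarray | None = None
    all_clusters: list[dict] = field(default_factory=list)
    target: ResidueKey | None = None
    target_centroid: np.ndarray | None = None


def define_shell(s: Structure, target: ResidueKey, radius: float = 5.0,
                 sequence: str | None = None) -> list[ResidueKey]:
    """Residues (heavy-atom criterion) within ``radius`` of the target.

    When a one-letter ``sequence`` is supplied (index 1 = first residue of
    the target's chain), residue names are cross-checked against it and a
    mismatch raises ValueError.
    """
    shell = structio.neighbors_within(s, target, radius)
    if sequence is not None:
        chain_keys = [k for k in s.residue_keys() if k.chain == target.chain]
        offset = min(k.residue_id for k in chain_keys)
        from ._tables import ONE_TO_THREE
        for key in shell:
            if key.chain != target.chain:
                continue
            pos = key.residue_id - offset
            if 0 <= pos < len(sequence):
                expected = ONE_TO_THREE.get(sequence[pos].upper())
                actual = s.residue_name_of(key)
                if expected and expected != actual:
                    raise ValueError(
                        f"sequence mismatch at {key}: structure has "
                        f"{actual}, sequence says {expected}")
    return shell


def _buriedness(empty: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Number of the 14 scan directions along which each voxel sees
    protein before leaving the grid."""
    counts = np.zeros(occupied.shape, dtype=np.int8)
    occ = occupied
    # axial: cumulative "any occupied further along the ray" via flips
    for axis in range(3):
        fwd = np.flip(np.maximum.accumulate(np.flip(occ, axis), axis), axis)
        bwd = np.maximum.accumulate(occ, axis)
        counts += fwd.astype(np.int8) + bwd.astype(np.int8)
    # diagonals: explicit stepping (grid dims are small)
    n = max(occupied.shape)
    for sx, sy, sz in _DIAGONAL:
        hit = np.zeros(occupied.shape, dtype=bool)
        shifted = occ.copy()
        for _ in range(n):
            shifted = _shift(shifted, sx, sy, sz)
            if not shifted.any():
                break
            hit |= shifted
        counts += hit.astype(np.int8)
    return np.where(empty, counts, 0)


def _shift(a: np.ndarray, sx: int, sy: int, sz: int) -> np.ndarray:
    """Shift a boolean grid by one voxel along (sx, sy, sz), zero-filled."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, step in enumerate((sx, sy, sz)):
        if step == 1:
            src[axis], dst[axis] = slice(0, -1), slice(1, None)
        elif step == -1:
            src[axis], dst[axis] = slice(1, None), slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def detect_pocket(s: Structure, shell: list[ResidueKey],
                  grid_spacing: float = 0.8, probe: float = 1.4,
                  buriedness_min: int = 9, margin: float = 4.0,
                  lining_distance: float | None = None,
                  target: ResidueKey | None = None,
                  min_volume: float = 10.0,
                  scan_spacing: float = 0.8) -> PocketReport:
    """Grid cavity detection seeded on the shell's bounding box.

    Voxels outside every atom+probe sphere but with buriedness >=
    ``buriedness_min`` (of 14 ray directions hitting protein) are cavity;
    connected cavity clusters of at least ``min_volume`` A^3 (single-voxel
    surface dimples are noise, not pockets) are reported and the one
    nearest the target becomes the pocket.

    Buriedness is always evaluated on a fixed-resolution scan grid
    (``scan_spacing``) so that whether a point in space counts as
    enclosed does not depend on the output voxel size; ``grid_spacing``
    only discretizes the volume integral and therefore converges as it
    shrinks.
    """
    if not shell:
        raise ValueError("empty shell")
    if target is None:
        target = shell_target(shell, s)
    target_centroid = _residue_centroid(s, target)

    heavy = np.nonzero(s.heavy_mask)[0]
    coords = s.coords[heavy]
    radii = s.vdw[heavy] + probe
    tree = cKDTree(coords)

    shell_idx = np.concatenate([s.atom_indices(k, heavy_only=True)
                                for k in shell])
    lo = s.coords[shell_idx].min(axis=0) - margin
    hi = s.coords[shell_idx].max(axis=0) + margin

    def _grid(spacing):
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        axes = [lo[d] + spacing * (np.arange(shape[d]) + 0.5)
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dist, nearest = tree.query(centers, k=1)
        occupied = (dist <= radii[nearest]).reshape(tuple(shape))
        return centers, occupied

    # classification pass at fixed resolution
    scan_centers, scan_occ = _grid(scan_spacing)
    scan_buried = _buriedness(~scan_occ, scan_occ)
    scan_cavity = (~scan_occ) & (scan_buried >= buriedness_min)

    # volume pass at the requested resolution, looking classification up
    # in the scan grid
    centers, occupied = _grid(grid_spacing)
    shape = occupied.shape
    empty = ~occupied
    idx = np.floor((centers - lo) / scan_spacing).astype(int)
    idx = np.minimum(np.maximum(idx, 0),
                     np.array(scan_cavity.shape) - 1)
    cavity = (scan_cavity[idx[:, 0], idx[:, 1], idx[:, 2]].reshape(shape)
              & empty)
    labels, n_lab = ndimage.label(cavity)
    clusters = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) * grid_spacing ** 3 < min_volume:
            continue
        pts = lo + (voxels + 0.5) * grid_spacing
        centroid = pts.mean(axis=0)
        clusters.append({
            "centroid": centroid,
            "volume": len(voxels) * grid_spacing ** 3,
            "n_voxels": len(voxels),
            "extent": pts.max(axis=0) - pts.min(axis=0) if len(pts) else None,
            "distance_to_target": float(np.linalg.norm(
                centroid - target_centroid)),
            "points": pts,
        })
    if not clusters:
        return PocketReport(shell, False, target=target,
                            target_centroid=target_centroid)

    clusters.sort(key=lambda c: c["distance_to_target"])
    best = clusters[0]
    lining_cut = (probe + 2.0) if lining_distance is None else lining_distance
    ptree = cKDTree(best["points"])
    lining: list[ResidueKey] = []
    for key in s.residue_keys():
        idx = s.atom_indices(key, heavy_only=True)
        if len(idx) and (ptree.query(s.coords[idx], k=1)[0] <= lining_cut).any():
            lining.append(key)
    report_clusters = [{k: v for k, v in c.items() if k != "points"}
                       for c in clusters]
    return PocketReport(shell, True, lining, best["volume"],
                        best["centroid"], report_clusters, target,
                        target_centroid)


def shell_target(shell: list[ResidueKey], s: Structure) -> ResidueKey:
    """The shell's target residue: by convention the first entry resolves;
    pocket callers build shells via define_shell which includes the
    target, so the centroid-nearest-to-all heuristic picks it back out."""
    centroids = np.array([_residue_centroid(s, k) for k in shell])
    mean = centroids.mean(axis=0)
    return shell[int(np.argmin(np.linalg.norm(centroids - mean, axis=1)))]


def _residue_centroid(s: Structure, key: ResidueKey) -> np.ndarray:
    idx = s.atom_indices(key, heavy_only=True)
    return s.coords[idx].mean(axis=0)


def emit_box(report: PocketReport, margin: float = 4.0) -> dict:
    """Axis-aligned docking box: pocket centroid + extent + 2*margin, or
    the target-residue centroid with minimal extent when no pocket."""
    if report.pocket_found:
        center = report.centroid
        extent = None
        for c in report.all_clusters:
            if np.allclose(c["centroid"], report.centroid):
                extent = c["extent"]
                break
        if extent is None:
            extent = np.zeros(3)
        edges = np.asarray(extent, dtype=float) + 2.0 * margin
    else:
        center = report.target_centroid
        edges = np.full(3, 2.0 * margin)
    return {"center_x": float(center[0]), "center_y": float(center[1]),
            "center_z": float(center[2]), "size_x": float(edges[0]),
            "size_y": float(edges[1]), "size_z": float(edges[2])}
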