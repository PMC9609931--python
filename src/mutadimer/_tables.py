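"""Built-in parameter tables.

All tables are plain dictionaries so downstream code (and users) can copy and
edit them; shape validation happens at the point of use, never value
validation — these are conventions, not measurements.
"""

from __future__ import annotations

# Element-keyed van der Waals radii (Angstrom), NACCESS/ProtOr-compatible
# convention for heavy atoms.  Unknown elements fall back to DEFAULT_VDW.
VDW_RADII: dict[str, float] = {
    "C": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "SE": 1.90,
}
DEFAULT_VDW = 1.8

# Average residue volumes (Angstrom^3), Zamyatnin-style consensus values.
RESIDUE_VOLUME: dict[str, float] = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

# Kyte-Doolittle hydropathy, used as the per-residue enthalpy-term table of
# the descriptor ddG model (Hdiff = H[mut] - H[wt]).
RESIDUE_HYDROPATHY: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# Gly-X-Gly reference solvent accessibilities (Angstrom^2) for relative-SASA
# normalisation (Tien et al. theoretical max set, rounded).
GXG_REFERENCE_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Coarse per-residue net charges, placed at the side-chain centroid by the
# simplified nonbonded potential.
RESIDUE_NET_CHARGE: dict[str, float] = {
    "ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0, "HIS": 0.1,
}

# Side-chain heavy-atom counts (full side chains, CB included); used by the
# contact-weighted ENM mutation proxy.
SIDECHAIN_HEAVY_ATOMS: dict[str, int] = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

# United-heavy-atom Lennard-Jones parameters per element: (sigma A, epsilon
# kcal/mol).  Combined with Lorentz-Berthelot rules.
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.10),
    "N": (3.25, 0.17),
    "O": (2.96, 0.21),
    "S": (3.50, 0.25),
    "P": (3.74, 0.20),
}
LJ_DEFAULT = (3.40, 0.10)

# Coarse allowed Ramachandran regions as (phi_min, phi_max, psi_min, psi_max)
# boxes in degrees, per residue class.  Deliberately generous: the check
# counts gross violations, it is not a validation-server reimplementation.
RAMACHANDRAN_BOXES: dict[str, list[tuple[float, float, float, float]]] = {
    "general": [
        (-180.0, -20.0, -120.0, 60.0),   # alpha / bridge
        (-180.0, -40.0, 60.0, 180.0),    # beta
        (-180.0, -40.0, -180.0, -150.0), # beta (psi wrap)
        (20.0, 100.0, -20.0, 90.0),      # left-handed alpha
    ],
    "GLY": [
        (-180.0, 180.0, -180.0, 180.0),  # glycine: effectively unrestricted
    ],
    "PRO": [
        (-110.0, -40.0, -75.0, 30.0),
        (-110.0, -40.0, 90.0, 180.0),
    ],
}

CANONICAL_RESIDUES = tuple(sorted(RESIDUE_VOLUME))

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
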