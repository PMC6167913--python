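"""Internal backbone geometry: dihedral-based chain construction and measurement.

Coordinates are in Angstrom throughout.  Chains are built atom by atom with
the standard internal-coordinate (NeRF) construction: each new atom is placed
at a fixed bond length and bond angle from the three previously placed atoms,
with the supplied torsion angle.
"""

from __future__ import annotations

import numpy as np

# Engh & Huber style backbone geometry constants (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> np.ndarray:
    """Build an N/CA/C/O backbone from per-residue (phi, psi) torsions.

    phi[0] and psi[-1] still shape the chain: phi[i] places C(i) relative to
    C(i-1) (so phi[0] is unused), psi[i] places N(i+1) and the carbonyl O(i).

    Returns coordinates of shape (n_residues, 4, 3), atom order N, CA, C, O.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n_res, OMEGA_TRANS)
    coords = np.zeros((n_res, 4, 3))
    # Seed frame for residue 0: N at origin, CA on x, C in the xy plane.
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        coords[i, 0] = place_atom(n_prev, ca_prev, c_prev,
                                  BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        coords[i, 1] = place_atom(ca_prev, c_prev, coords[i, 0],
                                  BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        coords[i, 2] = place_atom(c_prev, coords[i, 0], coords[i, 1],
                                  BOND_CA_C, ANGLE_N_CA_C, phi[i])
    # Carbonyl oxygens: anti to the next amide nitrogen about the C(i) plane,
    # which is torsion psi(i) + 180 about N(i)-CA(i)-C(i).
    for i in range(n_res):
        coords[i, 3] = place_atom(coords[i, 0], coords[i, 1], coords[i, 2],
                                  BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return coords


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def measure_backbone_torsions(coords: np.ndarray):
    """(phi, psi, omega) arrays from (n_res, 4, 3) backbone coordinates.

    Conventions match :func:`build_backbone`: phi[0] is a placeholder
    (-57), psi[-1] is recovered from the carbonyl oxygen, and omega[i]
    is the torsion placing CA(i+1).
    """
    n_res = coords.shape[0]
    N, CA, C, O = coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3]
    phi = np.empty(n_res)
    psi = np.empty(n_res)
    omega = np.full(n_res, OMEGA_TRANS)
    phi[0] = -57.0
    for i in range(n_res):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
            omega[i - 1] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
        if i < n_res - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
        else:
            psi[i] = dihedral(N[i], CA[i], C[i], O[i]) - 180.0
    return phi, psi, omega


def backbone_bond_lengths(coords: np.ndarray) -> np.ndarray:
    """Covalent backbone bond lengths for (n_res, 4, 3) coordinates.

    Order per residue: N-CA, CA-C, C-O, then C(i)-N(i+1) peptide bonds appended.
    """
    n = np.linalg.norm
    intra = np.stack([
        n(coords[:, 1] - coords[:, 0], axis=-1),
        n(coords[:, 2] - coords[:, 1], axis=-1),
        n(coords[:, 3] - coords[:, 2], axis=-1),
    ], axis=1).ravel()
    peptide = n(coords[1:, 0] - coords[:-1, 2], axis=-1)
    return np.concatenate([intra, peptide])
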