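"""Ideal-geometry backbone construction (NeRF) used by the synthetic complexes.

Bond lengths and angles are the standard Engh–Huber-style values; chains are
grown residue by residue from (phi, psi, omega) torsions. Only backbone
N, CA, C, O plus a CB stub are produced — enough for solvent accessibility,
contacts, hydrogen-bond geometry and secondary-structure patterns, with no
pretence of side-chain realism.
"""

from __future__ import annotations

import numpy as np

# bond lengths (Angstrom) and angles (degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.1

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-140.0, 140.0)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c, with angle b-c-d and dihedral a-b-c-d."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0) -> dict[str, np.ndarray]:
    """Build an ideal-geometry backbone with uniform torsions.

    Returns arrays of shape (n_res, 3) for N, CA, C, O and CB.
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))

    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [B_N_CA, 0.0, 0.0]
    ang = np.deg2rad(A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = nerf(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi)
        CA[i + 1] = nerf(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, omega)
        C[i + 1] = nerf(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi)
        O[i] = nerf(N[i + 1], CA[i], C[i], B_C_O, A_CA_C_O, 180.0)
    # last carbonyl oxygen: trans to the chain direction
    O[-1] = nerf(N[-1], CA[-1], C[-1], B_C_O, A_CA_C_O, 180.0 + psi)

    for i in range(n_res):
        CB[i] = nerf(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, -122.6)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit direction of the first principal component, oriented head-to-tail."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the half-turn
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return rodrigues(axis, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    return rodrigues(axis, float(np.arctan2(s, c)))


def rodrigues(axis: np.ndarray, theta: float) -> np.ndarray:
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def place_segment(atoms: dict[str, np.ndarray], origin: np.ndarray,
                  direction: np.ndarray, phase: float = 0.0) -> dict[str, np.ndarray]:
    """Rigidly place a built segment: its CA principal axis along ``direction``
    starting at ``origin``, with an extra roll of ``phase`` radians about
    the axis."""
    axis = principal_axis(atoms["CA"])
    R = rotation_between(axis, direction)
    if phase:
        R = rodrigues(np.asarray(direction, dtype=float) /
                      np.linalg.norm(direction), phase) @ R
    start = atoms["CA"][0]
    out = {}
    for name, xyz in atoms.items():
        out[name] = (xyz - start) @ R.T + origin
    return out
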