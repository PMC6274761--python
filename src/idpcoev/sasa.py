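"""Shrake–Rupley solvent-accessible surface area.

Each heavy atom is covered with a quasi-uniform sphere of test points at
radius vdW + probe; points buried inside any neighbouring atom's expanded
sphere are removed and the surviving fraction of the sphere area is the
atom's SASA. 960 points per atom is the working default; a denser sphere
(e.g. 5000 points) serves as a refinement reference.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def sphere_points(n: int) -> np.ndarray:
    """Fibonacci-spiral unit sphere points (quasi-uniform)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def atom_sasa(coords: np.ndarray, elements: list[str],
              n_points: int = DEFAULT_N_POINTS,
              probe: float = PROBE_RADIUS) -> np.ndarray:
    """Per-atom SASA (Å²) of a heavy-atom selection."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    radii = np.array([vdw_radius(e) for e in elements]) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.zeros(n_atoms)
    for a in range(n_atoms):
        pts = coords[a] + radii[a] * unit
        neighbours = tree.query_ball_point(coords[a], radii[a] + max_r)
        neighbours = [b for b in neighbours if b != a]
        exposed = np.ones(n_points, dtype=bool)
        for b in neighbours:
            d2 = ((pts - coords[b]) ** 2).sum(axis=1)
            exposed &= d2 > radii[b] ** 2
        out[a] = exposed.mean() * 4.0 * np.pi * radii[a] ** 2
    return out


def residue_sasa(structure, atom_mask: np.ndarray,
                 n_points: int = DEFAULT_N_POINTS) -> dict[int, float]:
    """Per-residue SASA of the atoms selected by ``atom_mask``, computed in
    the context of that selection only (other atoms do not occlude)."""
    idx = np.where(atom_mask)[0]
    values = atom_sasa(structure.coords[idx],
                       [structure.elements[a] for a in idx], n_points)
    per_res: dict[int, float] = {}
    for a, v in zip(idx, values):
        ri = int(structure.atom_res_index[a])
        per_res[ri] = per_res.get(ri, 0.0) + float(v)
    return per_res
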