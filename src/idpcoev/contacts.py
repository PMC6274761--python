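"""Interchain atomic contact maps.

Two heavy atoms from different chains are in contact when their distance is
at most the sum of their van der Waals radii plus a 0.5 Å slack; the contact
count of a residue pair is the number of such atom pairs. Contacts of the
same partner residue arriving from multiple identical partner chains are
added up, as are per-residue totals across all partner residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sasa import vdw_radius
from .structure import ComplexStructure

CONTACT_SLACK = 0.5  # Å added to the vdW-radius sum


@dataclass
class ContactMap:
    """Residue-pair atomic contact counts between the IDP and its partners.

    Keys of ``entries`` are (idp resseq, partner resseq) — partner chains are
    merged by residue number, so identical chains accumulate. Per-residue
    totals sum each side's entries.
    """

    entries: dict[tuple[int, int], int] = field(default_factory=dict)
    min_distance: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def idp_totals(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (i, _), n in self.entries.items():
            out[i] = out.get(i, 0) + n
        return out

    @property
    def partner_totals(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (_, j), n in self.entries.items():
            out[j] = out.get(j, 0) + n
        return out

    def total(self) -> int:
        return sum(self.entries.values())


def atomic_contacts(s: ComplexStructure, slack: float = CONTACT_SLACK) -> ContactMap:
    """Count interchain heavy-atom contacts between the IDP chain and all
    partner chains using a vdW-sum + slack criterion."""
    idp_atoms = np.where(s.chain_atom_mask(s.idp_chain))[0]
    cmap = ContactMap()
    if len(idp_atoms) == 0:
        return cmap
    idp_radii = np.array([vdw_radius(s.elements[a]) for a in idp_atoms])
    idp_tree = cKDTree(s.coords[idp_atoms])

    for c in s.partner_chains:
        p_atoms = np.where(s.chain_atom_mask(c))[0]
        if len(p_atoms) == 0:
            continue
        p_radii = np.array([vdw_radius(s.elements[a]) for a in p_atoms])
        max_cut = idp_radii.max() + p_radii.max() + slack
        pairs = idp_tree.query_ball_point(s.coords[p_atoms], max_cut)
        for kp, near in enumerate(pairs):
            if not near:
                continue
            b = p_atoms[kp]
            rj = s.residues[int(s.atom_res_index[b])].resseq
            for ka in near:
                a = idp_atoms[ka]
                d = float(np.linalg.norm(s.coords[a] - s.coords[b]))
                if d <= idp_radii[ka] + p_radii[kp] + slack:
                    ri = s.residues[int(s.atom_res_index[a])].resseq
                    key = (ri, rj)
                    cmap.entries[key] = cmap.entries.get(key, 0) + 1
                    if key not in cmap.min_distance or d < cmap.min_distance[key]:
                        cmap.min_distance[key] = d
    return cmap


def brute_force_contacts(s: ComplexStructure, slack: float = CONTACT_SLACK) -> ContactMap:
    """All-pairs O(n²) reference implementation (oracle for the grid version)."""
    cmap = ContactMap()
    idp_atoms = np.where(s.chain_atom_mask(s.idp_chain))[0]
    for c in s.partner_chains:
        p_atoms = np.where(s.chain_atom_mask(c))[0]
        for a in idp_atoms:
            ra = vdw_radius(s.elements[a])
            ri = s.residues[int(s.atom_res_index[a])].resseq
            for b in p_atoms:
                d = float(np.linalg.norm(s.coords[a] - s.coords[b]))
                if d <= ra + vdw_radius(s.elements[b]) + slack:
                    rj = s.residues[int(s.atom_res_index[b])].resseq
                    key = (ri, rj)
                    cmap.entries[key] = cmap.entries.get(key, 0) + 1
                    if key not in cmap.min_distance or d < cmap.min_distance[key]:
                        cmap.min_distance[key] = d
    return cmap
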