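"""Interface assignment and interchain bond detection.

Interfaces are derived geometrically from solvent accessibility: a residue
is an interface residue when burying it in the complex removes more than
0.1 Å² of the accessible area it has in its isolated chain, and the pairwise
interface area between the IDP chain and one partner chain is half the total
SASA lost on complexation. Hydrogen bonds are counted between interchain
N/O heavy-atom pairs within 3.5 Å, salt bridges between basic side-chain
nitrogens (Lys NZ, Arg NH1/NH2/NE, His ND1/NE2) and acidic side-chain
oxygens (Asp OD1/OD2, Glu OE1/OE2) within 4.0 Å; a contact can count in
both categories. These are documented geometric surrogates for a buried-
surface service's assignments; an override table can replace them when
reference interface assignments are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .sasa import DEFAULT_N_POINTS, residue_sasa
from .structure import ComplexStructure

DELTA_SASA_MIN = 0.1  # Å² buried to call a residue interfacial
HBOND_MAX = 3.5
SALT_BRIDGE_MAX = 4.0

BASIC_ATOMS = {("K", "NZ"), ("R", "NH1"), ("R", "NH2"), ("R", "NE"),
               ("H", "ND1"), ("H", "NE2")}
ACIDIC_ATOMS = {("D", "OD1"), ("D", "OD2"), ("E", "OE1"), ("E", "OE2")}


@dataclass
class Interface:
    """Per-complex interface summary.

    Residues are indices into ``structure.residues``; ``total_area`` sums the
    pairwise IDP-partner interface areas over partner chains (Å²).
    """

    idp_if_residues: set[int]
    partner_if_residues: set[int]
    total_area: float
    pairwise_area: dict[str, float] = field(default_factory=dict)
    hbonds: list[tuple[int, int, float]] = field(default_factory=list)
    salt_bridges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_bonds(self) -> int:
        return len(self.hbonds) + len(self.salt_bridges)

    @property
    def bonds_per_1000A2(self) -> float:
        if self.total_area <= 0:
            return 0.0
        return 1000.0 * self.n_bonds / self.total_area


def assign_interface(s: ComplexStructure,
                     n_points: int = DEFAULT_N_POINTS) -> Interface:
    """ΔSASA interface assignment between the IDP chain and each partner chain."""
    chains = [s.idp_chain] + s.partner_chains
    complex_mask = np.zeros(s.n_atoms(), dtype=bool)
    for c in chains:
        complex_mask |= s.chain_atom_mask(c)
    sasa_complex = residue_sasa(s, complex_mask, n_points)
    alone: dict[str, dict[int, float]] = {}
    for c in chains:
        alone[c] = residue_sasa(s, s.chain_atom_mask(c), n_points)

    idp_if: set[int] = set()
    partner_if: set[int] = set()
    for c in chains:
        target = idp_if if c == s.idp_chain else partner_if
        for ri, area_alone in alone[c].items():
            if area_alone - sasa_complex.get(ri, 0.0) > DELTA_SASA_MIN:
                target.add(ri)

    pairwise: dict[str, float] = {}
    idp_mask = s.chain_atom_mask(s.idp_chain)
    idp_alone_total = sum(alone[s.idp_chain].values())
    for c in s.partner_chains:
        pair_mask = idp_mask | s.chain_atom_mask(c)
        sasa_pair = sum(residue_sasa(s, pair_mask, n_points).values())
        partner_alone_total = sum(alone[c].values())
        area = 0.5 * (idp_alone_total + partner_alone_total - sasa_pair)
        # snap numerical residue to an exact zero for truly disjoint chains
        pairwise[c] = area if area > 1e-6 else 0.0
    iface = Interface(
        idp_if_residues=idp_if,
        partner_if_residues=partner_if,
        total_area=float(sum(pairwise.values())),
        pairwise_area=pairwise,
    )
    hb, sb = detect_bonds(s, iface)
    iface.hbonds = hb
    iface.salt_bridges = sb
    return iface


def load_interface_override(path: str | Path, s: ComplexStructure) -> Interface:
    """Read a reference interface table (TSV: chain, resseq, is_interface,
    area_contrib) in place of the geometric assignment."""
    idp_if: set[int] = set()
    partner_if: set[int] = set()
    total = 0.0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "chain\t")):
            continue
        chain, resseq, is_if, area = line.split("\t")
        ri = s.residue_index(chain, int(resseq))
        if ri is None or int(is_if) == 0:
            continue
        (idp_if if chain == s.idp_chain else partner_if).add(ri)
        total += float(area)
    iface = Interface(idp_if, partner_if, total)
    hb, sb = detect_bonds(s, iface)
    iface.hbonds = hb
    iface.salt_bridges = sb
    return iface


def detect_bonds(s: ComplexStructure, interface: Interface | None = None
                 ) -> tuple[list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    """Interchain H-bonds and salt bridges between the IDP and partner chains.

    Returns (hbonds, salt_bridges) as (idp residue index, partner residue
    index, distance) lists; a geometry satisfying both criteria appears once
    in each list.
    """
    idp_atoms = np.where(s.chain_atom_mask(s.idp_chain))[0]
    partner_mask = np.zeros(s.n_atoms(), dtype=bool)
    for c in s.partner_chains:
        partner_mask |= s.chain_atom_mask(c)
    partner_atoms = np.where(partner_mask)[0]
    if len(idp_atoms) == 0 or len(partner_atoms) == 0:
        return [], []

    tree = cKDTree(s.coords[partner_atoms])
    hbonds: dict[tuple[int, int], float] = {}
    bridges: dict[tuple[int, int], float] = {}
    for a in idp_atoms:
        ea = s.elements[a]
        if ea not in ("N", "O"):
            continue
        ri = int(s.atom_res_index[a])
        aa_a = s.residues[ri].aa
        name_a = s.atom_names[a]
        for k in tree.query_ball_point(s.coords[a], SALT_BRIDGE_MAX):
            b = partner_atoms[k]
            eb = s.elements[b]
            if eb not in ("N", "O"):
                continue
            rj = int(s.atom_res_index[b])
            aa_b = s.residues[rj].aa
            d = float(np.linalg.norm(s.coords[a] - s.coords[b]))
            key = (ri, rj)
            if d <= HBOND_MAX:
                if key not in hbonds or d < hbonds[key]:
                    hbonds[key] = d
            ab = ((aa_a, name_a), (aa_b, s.atom_names[b]))
            ionic = ((ab[0] in BASIC_ATOMS and ab[1] in ACIDIC_ATOMS)
                     or (ab[0] in ACIDIC_ATOMS and ab[1] in BASIC_ATOMS))
            if ionic and d <= SALT_BRIDGE_MAX:
                if key not in bridges or d < bridges[key]:
                    bridges[key] = d
    hb = sorted((i, j, d) for (i, j), d in hbonds.items())
    sb = sorted((i, j, d) for (i, j), d in bridges.items())
    return hb, sb
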