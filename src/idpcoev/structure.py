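"""Complex-structure container, PDB/mmCIF I/O, distances and EC visibility.

A :class:`ComplexStructure` holds heavy atoms of one IDP chain bound to one
or more (identical) folded partner chains, together with the explicit
UniProt-to-structure numbering map needed to place alignment-derived residue
pairs onto the structure. Couplings whose residues fall outside the resolved
part of the structure are "invisible": either the residue was never in the
crystallised construct, or it was in the construct but has no coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .alphabet import ONE_TO_THREE, THREE_TO_ONE

VISIBLE = "visible"
NOT_IN_CONSTRUCT = "not_in_construct"
NO_COORDINATES = "no_coordinates"


@dataclass(frozen=True)
class ResidueKey:
    chain: str
    resseq: int
    icode: str = ""
    aa: str = "X"  # one-letter code, 'X' if unknown


class NumberingMap:
    """UniProt position <-> (chain, resseq) correspondence, per chain.

    Built from per-chain offsets or explicit tables; injective per chain.
    """

    def __init__(self, table: dict[str, dict[int, int]]):
        # table[chain][uniprot_pos] = resseq
        self.table = {c: dict(m) for c, m in table.items()}
        for chain, m in self.table.items():
            if len(set(m.values())) != len(m):
                raise ValueError(f"numbering map not injective for chain {chain}")
        self._inverse = {
            c: {r: u for u, r in m.items()} for c, m in self.table.items()
        }

    @classmethod
    def from_offset(cls, chain_ranges: dict[str, tuple[int, int, int]]) -> "NumberingMap":
        """chain -> (uniprot_start, uniprot_end, resseq_of_start)."""
        table = {}
        for chain, (u0, u1, r0) in chain_ranges.items():
            table[chain] = {u: r0 + (u - u0) for u in range(u0, u1 + 1)}
        return cls(table)

    def to_structure(self, chain: str, uniprot_pos: int) -> int | None:
        return self.table.get(chain, {}).get(uniprot_pos)

    def to_uniprot(self, chain: str, resseq: int) -> int | None:
        return self._inverse.get(chain, {}).get(resseq)

    def chains(self) -> list[str]:
        return list(self.table)


class ComplexStructure:
    """Heavy-atom model of an IDP chain bound to folded partner chain(s)."""

    def __init__(
        self,
        residues: list[ResidueKey],
        atom_names: list[str],
        elements: list[str],
        coords: np.ndarray,
        atom_res_index: np.ndarray,
        idp_chain: str,
        partner_chains: list[str],
        numbering_map: NumberingMap | None = None,
        is_nmr: bool = False,
    ):
        self.residues = residues
        self.atom_names = list(atom_names)
        self.elements = [e.upper() for e in elements]
        self.coords = np.asarray(coords, dtype=float)
        self.atom_res_index = np.asarray(atom_res_index, dtype=int)
        self.idp_chain = idp_chain
        self.partner_chains = list(partner_chains)
        self.numbering_map = numbering_map
        self.is_nmr = is_nmr
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite atom coordinates")

        self._res_lookup: dict[tuple[str, int, str], int] = {}
        for i, rk in enumerate(residues):
            self._res_lookup[(rk.chain, rk.resseq, rk.icode)] = i
        self._res_atoms: list[list[int]] = [[] for _ in residues]
        for a, ri in enumerate(self.atom_res_index):
            self._res_atoms[ri].append(a)

    # ---- lookups ----------------------------------------------------------

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for rk in self.residues:
            if rk.chain not in seen:
                seen.append(rk.chain)
        return seen

    def residue_index(self, chain: str, resseq: int, icode: str = "") -> int | None:
        return self._res_lookup.get((chain, resseq, icode))

    def atom_indices(self, res_index: int) -> list[int]:
        return self._res_atoms[res_index]

    def residue_coords(self, res_index: int) -> np.ndarray:
        return self.coords[self._res_atoms[res_index]]

    def has_coordinates(self, chain: str, resseq: int) -> bool:
        ri = self.residue_index(chain, resseq)
        return ri is not None and len(self._res_atoms[ri]) > 0

    def chain_residue_indices(self, chain: str) -> list[int]:
        return [i for i, rk in enumerate(self.residues) if rk.chain == chain]

    def chain_atom_mask(self, chain: str) -> np.ndarray:
        res_is_chain = np.array([rk.chain == chain for rk in self.residues])
        return res_is_chain[self.atom_res_index]

    def n_atoms(self) -> int:
        return len(self.atom_names)

    def backbone(self, res_index: int) -> dict[str, np.ndarray] | None:
        """N/CA/C/O coordinates of a residue, or None if incomplete."""
        out = {}
        for a in self._res_atoms[res_index]:
            name = self.atom_names[a]
            if name in ("N", "CA", "C", "O"):
                out[name] = self.coords[a]
        if set(out) >= {"N", "CA", "C", "O"}:
            return out
        return None

    # ---- output -----------------------------------------------------------

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = "idpcoev"
        model = gemmi.Model("1")
        by_chain: dict[str, gemmi.Chain] = {}
        for ri, rk in enumerate(self.residues):
            if rk.chain not in by_chain:
                by_chain[rk.chain] = gemmi.Chain(rk.chain)
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(rk.aa, "UNK")
            res.seqid = gemmi.SeqId(rk.resseq, rk.icode if rk.icode else " ")
            for a in self._res_atoms[ri]:
                atom = gemmi.Atom()
                atom.name = self.atom_names[a]
                atom.element = gemmi.Element(self.elements[a])
                atom.pos = gemmi.Position(*self.coords[a])
                atom.occ = 1.0
                res.add_atom(atom)
            by_chain[rk.chain].add_residue(res)
        for chain in by_chain.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str | Path) -> None:
        self.to_gemmi().write_pdb(str(path))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path,
    idp_chain: str,
    partner_chains: list[str],
    numbering_map: NumberingMap | None = None,
    expected_sequences: dict[str, dict[int, str]] | None = None,
) -> ComplexStructure:
    """Load a PDB/mmCIF file into a :class:`ComplexStructure`.

    Only heavy atoms are kept; alternate locations are resolved to the
    highest-occupancy conformer; for multi-model (NMR) files the first model
    is used and the structure is flagged ``is_nmr``. ``expected_sequences``
    (chain -> {uniprot_pos: one-letter aa}) cross-checks the numbering map
    against residue identities.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_ligands_and_waters()
    is_nmr = len(st) > 1
    model = st[0]
    wanted = [idp_chain] + list(partner_chains)
    available = [ch.name for ch in model]
    for chain in wanted:
        if chain not in available:
            raise ValueError(f"chain {chain!r} not in structure (available: {available})")

    residues: list[ResidueKey] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    atom_res_index: list[int] = []
    for chain in model:
        if chain.name not in wanted:
            continue
        for res in chain:
            if res.name not in THREE_TO_ONE:
                continue
            aa = THREE_TO_ONE[res.name]
            icode = res.seqid.icode.strip()
            rk = ResidueKey(chain.name, res.seqid.num, icode, aa)
            ri = len(residues)
            residues.append(rk)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                atom_names.append(name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                atom_res_index.append(ri)

    s = ComplexStructure(
        residues, atom_names, elements,
        np.asarray(coords, dtype=float).reshape(-1, 3),
        np.asarray(atom_res_index, dtype=int),
        idp_chain, list(partner_chains), numbering_map, is_nmr,
    )
    if numbering_map is not None and expected_sequences:
        _validate_map(s, numbering_map, expected_sequences)
    return s


def _validate_map(s: ComplexStructure, nmap: NumberingMap,
                  expected: dict[str, dict[int, str]]) -> None:
    for chain, seq in expected.items():
        for upos, aa in seq.items():
            resseq = nmap.to_structure(chain, upos)
            if resseq is None:
                continue
            ri = s.residue_index(chain, resseq)
            if ri is not None and s.residues[ri].aa not in (aa, "X"):
                raise ValueError(
                    f"numbering map mismatch at chain {chain} UniProt {upos}: "
                    f"expected {aa}, structure has {s.residues[ri].aa}"
                )


# ---------------------------------------------------------------------------
# distances & visibility
# ---------------------------------------------------------------------------


def residue_min_distance(s: ComplexStructure, res_a: int, res_b: int) -> float:
    """Shortest heavy-atom distance between two residues (indices into
    ``s.residues``); a residue against itself gives 0."""
    if res_a == res_b:
        return 0.0
    xa = s.residue_coords(res_a)
    xb = s.residue_coords(res_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("residue without coordinates; check visibility first")
    return float(cdist(xa, xb).min())


def classify_visibility(ec, s: ComplexStructure) -> tuple[str, str | None]:
    """Classify an interprotein coupling against the structure.

    Returns ``("visible", None)`` when both residues have coordinates, else
    ``("invisible", reason)`` with reason ``not_in_construct`` (position not
    covered by the numbering map) or ``no_coordinates`` (in the construct but
    unresolved). The IDP side is checked against the IDP chain; the partner
    side is visible if any partner chain resolves it.
    """
    nmap = s.numbering_map
    if nmap is None:
        raise ValueError("structure has no numbering map")

    def check(pos: int, chains: list[str]) -> str:
        mapped = False
        for chain in chains:
            resseq = nmap.to_structure(chain, pos)
            if resseq is None:
                continue
            mapped = True
            if s.has_coordinates(chain, resseq):
                return VISIBLE
        return NO_COORDINATES if mapped else NOT_IN_CONSTRUCT

    idp_status = check(ec.idp_uniprot_pos, [s.idp_chain])
    partner_status = check(ec.partner_uniprot_pos, s.partner_chains)
    for status in (NOT_IN_CONSTRUCT, NO_COORDINATES):
        if idp_status == status or partner_status == status:
            return ("invisible", status)
    return (VISIBLE, None)


def ec_structure_residues(ec, s: ComplexStructure) -> tuple[int, int] | None:
    """Residue indices of a visible coupling (IDP residue, closest-mapped
    partner residue); None when invisible."""
    nmap = s.numbering_map
    idp_resseq = nmap.to_structure(s.idp_chain, ec.idp_uniprot_pos)
    if idp_resseq is None or not s.has_coordinates(s.idp_chain, idp_resseq):
        return None
    ri = s.residue_index(s.idp_chain, idp_resseq)
    best = None
    for chain in s.partner_chains:
        resseq = nmap.to_structure(chain, ec.partner_uniprot_pos)
        if resseq is None or not s.has_coordinates(chain, resseq):
            continue
        rj = s.residue_index(chain, resseq)
        d = residue_min_distance(s, ri, rj)
        if best is None or d < best[1]:
            best = (rj, d)
    if best is None:
        return None
    return (ri, best[0])
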