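"""Secondary-structure assignment: simplified Kabsch–Sander, plus a reader
for standard DSSP output files (which takes precedence when available).

Backbone amide hydrogens are reconstructed from geometry, hydrogen bonds are
scored with the Kabsch–Sander electrostatic energy
E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol (bond if
E < -0.5), and the classic patterns produce the 8-state codes: runs of
i -> i+4 turns give H, i -> i+3 gives G, i -> i+5 gives I, bridge patterns
give E (ladders) or B (isolated), remaining turns T, bends S, else C. The
8 states group into three classes: G/H/I -> helix, E/B -> strand,
S/T/C -> loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import ComplexStructure

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
KS_FACTOR = 0.084 * 332.0
CLASS_OF = {"G": "helix", "H": "helix", "I": "helix",
            "E": "strand", "B": "strand",
            "S": "loop", "T": "loop", "C": "loop"}


@dataclass
class SSAssignment:
    """Per-residue 8-state codes (indices into ``structure.residues``)."""

    codes: dict[int, str] = field(default_factory=dict)

    def three_class(self, res_index: int) -> str:
        return CLASS_OF[self.codes.get(res_index, "C")]

    def counts_by_class(self, residue_indices=None) -> dict[str, int]:
        idx = self.codes.keys() if residue_indices is None else residue_indices
        out = {"helix": 0, "strand": 0, "loop": 0}
        for ri in idx:
            out[self.three_class(ri)] += 1
        return out


def _chain_runs(s: ComplexStructure) -> list[list[int]]:
    """Residue indices grouped by chain, in file order (assumed sequential)."""
    runs: dict[str, list[int]] = {}
    for ri, rk in enumerate(s.residues):
        runs.setdefault(rk.chain, []).append(ri)
    return list(runs.values())


def assign_secondary_structure(s: ComplexStructure) -> SSAssignment:
    """Simplified Kabsch–Sander assignment over all chains of the complex."""
    n = len(s.residues)
    bb = [s.backbone(ri) for ri in range(n)]
    incomplete = [ri for ri in range(n) if bb[ri] is None and s.atom_indices(ri)]
    if incomplete:
        warnings.warn(f"{len(incomplete)} residues lack full backbone; assigned C")

    runs = _chain_runs(s)
    pos_in_chain: dict[int, tuple[int, int]] = {}
    for ci, run in enumerate(runs):
        for k, ri in enumerate(run):
            pos_in_chain[ri] = (ci, k)

    # reconstructed amide H: N + 1.01 * bisector of (N-C_prev, N-CA)
    H: dict[int, np.ndarray] = {}
    for ci, run in enumerate(runs):
        for k, ri in enumerate(run):
            if bb[ri] is None or k == 0 or s.residues[ri].aa == "P":
                continue
            prev = run[k - 1]
            if bb[prev] is None:
                continue
            u = bb[ri]["N"] - bb[prev]["C"]
            v = bb[ri]["N"] - bb[ri]["CA"]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            w = u + v
            H[ri] = bb[ri]["N"] + 1.01 * w / np.linalg.norm(w)

    def hb(acceptor: int, donor: int) -> bool:
        """CO(acceptor) ... NH(donor) Kabsch-Sander bond."""
        if bb[acceptor] is None or bb[donor] is None or donor not in H:
            return False
        C, O = bb[acceptor]["C"], bb[acceptor]["O"]
        N, Hd = bb[donor]["N"], H[donor]
        r_on = np.linalg.norm(O - N)
        if r_on > 5.2:
            return False
        e = KS_FACTOR * (1.0 / r_on + 1.0 / np.linalg.norm(C - Hd)
                         - 1.0 / np.linalg.norm(O - Hd) - 1.0 / np.linalg.norm(C - N))
        return e < HB_ENERGY_CUTOFF

    # candidate pairs limited by CA proximity
    ca = np.array([bb[ri]["CA"] if bb[ri] is not None else [1e6, 1e6, 1e6]
                   for ri in range(n)])
    from scipy.spatial import cKDTree
    tree = cKDTree(ca)
    near = tree.query_pairs(9.0)

    hbond: set[tuple[int, int]] = set()  # (acceptor, donor)
    for a, b in near:
        if hb(a, b):
            hbond.add((a, b))
        if hb(b, a):
            hbond.add((b, a))

    codes = {ri: "C" for ri in range(n) if s.atom_indices(ri)}

    def turn(i_ri: int, nres: int) -> bool:
        ci, k = pos_in_chain[i_ri]
        run = runs[ci]
        if k + nres >= len(run):
            return False
        return (i_ri, run[k + nres]) in hbond

    # helices from consecutive n-turns; priority H > (bridges) > G > I
    marks: dict[str, set[int]] = {"H": set(), "G": set(), "I": set()}
    for code, nres in (("H", 4), ("G", 3), ("I", 5)):
        for run in runs:
            for k in range(1, len(run)):
                if turn(run[k], nres) and turn(run[k - 1], nres):
                    marks[code].update(run[k + d] for d in range(nres)
                                       if k + d < len(run))

    # bridges (parallel / antiparallel), any chain pair, non-local in sequence
    def neighbours(ri: int, d: int) -> int | None:
        ci, k = pos_in_chain[ri]
        run = runs[ci]
        return run[k + d] if 0 <= k + d < len(run) else None

    bridge_partners: dict[int, set[int]] = {}
    for i, j in near:
        ci, ki = pos_in_chain[i]
        cj, kj = pos_in_chain[j]
        if ci == cj and abs(ki - kj) < 3:
            continue
        im, ip = neighbours(i, -1), neighbours(i, 1)
        jm, jp = neighbours(j, -1), neighbours(j, 1)
        para = False
        if im is not None and ip is not None:
            para |= (im, j) in hbond and (j, ip) in hbond
        if jm is not None and jp is not None:
            para |= (jm, i) in hbond and (i, jp) in hbond
        anti = (i, j) in hbond and (j, i) in hbond
        if all(x is not None for x in (im, ip, jm, jp)):
            anti |= (im, jp) in hbond and (jm, ip) in hbond
        if para or anti:
            bridge_partners.setdefault(i, set()).add(j)
            bridge_partners.setdefault(j, set()).add(i)

    strand: set[int] = set()
    isolated: set[int] = set()
    for ri in bridge_partners:
        ci, k = pos_in_chain[ri]
        run = runs[ci]
        prev_b = run[k - 1] in bridge_partners if k > 0 else False
        next_b = run[k + 1] in bridge_partners if k + 1 < len(run) else False
        (strand if (prev_b or next_b) else isolated).add(ri)

    # turns not in helices
    turn_res: set[int] = set()
    for run in runs:
        for k, ri in enumerate(run):
            for nres in (3, 4, 5):
                if turn(ri, nres):
                    turn_res.update(run[k + d] for d in range(1, nres)
                                    if k + d < len(run))

    # bends: CA virtual-bond kink > 70 degrees
    bend: set[int] = set()
    for run in runs:
        for k in range(2, len(run) - 2):
            ri = run[k]
            if any(bb[r] is None for r in (run[k - 2], ri, run[k + 2])):
                continue
            u = ca[ri] - ca[run[k - 2]]
            v = ca[run[k + 2]] - ca[ri]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70:
                bend.add(ri)

    for ri in list(codes):
        if bb[ri] is None:
            codes[ri] = "C"
        elif ri in marks["H"]:
            codes[ri] = "H"
        elif ri in strand:
            codes[ri] = "E"
        elif ri in isolated:
            codes[ri] = "B"
        elif ri in marks["G"]:
            codes[ri] = "G"
        elif ri in marks["I"]:
            codes[ri] = "I"
        elif ri in turn_res:
            codes[ri] = "T"
        elif ri in bend:
            codes[ri] = "S"
    return SSAssignment(codes)


def read_dssp(path: str | Path, s: ComplexStructure) -> SSAssignment:
    """Parse a classic DSSP output file into per-residue codes, matched to the
    structure by (chain, resseq). Blank DSSP codes map to C."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(k for k, ln in enumerate(lines) if ln.startswith("  #  RESIDUE"))
    except StopIteration as exc:
        raise ValueError("not a DSSP output file (missing residue header)") from exc
    codes: dict[int, str] = {}
    for ln in lines[start + 1:]:
        if len(ln) < 17 or ln[13] == "!":
            continue
        resseq = int(ln[5:10])
        chain = ln[11].strip()
        code = ln[16].strip() or "C"
        ri = s.residue_index(chain, resseq)
        if ri is not None:
            codes[ri] = code if code in CLASS_OF else "C"
    return SSAssignment(codes)
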