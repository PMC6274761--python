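"""21-state amino-acid alphabet shared by the alignment and Potts-model code.

The state space is the 20 standard amino acids plus one gap state. Any
non-standard or unknown letter (B, Z, X, J, O, U, '.', '*', ...) maps to the
gap state, which keeps column statistics well defined on real alignments.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
Q = len(ALPHABET)  # 21
GAP_STATE = Q - 1  # index of the gap state

_LUT = np.full(128, GAP_STATE, dtype=np.int8)
for _i, _c in enumerate(AMINO_ACIDS):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

# residue group partition used throughout the composition analysis
RESIDUE_GROUPS = {
    "hydrophobic": set("GAVLMI"),
    "aromatic": set("FYW"),
    "polar": set("STCPNQ"),
    "negative": set("DE"),
    "positive": set("KRH"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string into int8 state indices (gap = 20)."""
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _LUT[np.minimum(arr, 127)]


def decode(states: np.ndarray) -> str:
    return "".join(ALPHABET[s] for s in states)


def residue_group(aa: str) -> str:
    for name, members in RESIDUE_GROUPS.items():
        if aa in members:
            return name
    raise ValueError(f"not a standard amino acid: {aa!r}")
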