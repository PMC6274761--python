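"""Dataset preparation: region trimming/extension, family-size gating,
paired-alignment construction and sequence reweighting.

These are the bookkeeping rules applied before any co-variation analysis:

* short IDP regions are extended along the UniProt sequence to a minimum
  length (30 residues by default), because coupling analysis needs a minimum
  segment length;
* complexes whose IDP family has too few homologous sequences (< 130 in the
  full family alignment by default) are excluded — without sequence diversity
  there is no co-variation signal to measure;
* per-species closest homologs of the two proteins are concatenated into a
  paired alignment;
* near-duplicate rows are down-weighted so that the effective sample size
  reflects sequence diversity rather than database redundancy.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .alignment import PairedAlignment
from .alphabet import GAP_STATE, encode

DEFAULT_MIN_LEN = 30
DEFAULT_PFAM_THRESHOLD = 130
DEFAULT_IDENTITY_THRESHOLD = 0.8


class CoordinateError(ValueError):
    """Region coordinates fall outside the parent sequence."""


@dataclass(frozen=True)
class TrimmedRegion:
    """A UniProt region selected (and possibly extended) for analysis.

    ``start``/``end`` are 1-based inclusive UniProt coordinates;
    ``extension_added`` records how many residues were prepended (n_term)
    and appended (c_term) relative to the originally annotated region.
    """

    uniprot_ac: str
    start: int
    end: int
    sequence: str
    role: str = "idp"  # "idp" | "partner"
    extension_added: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(f"{self.uniprot_ac}: end {self.end} < start {self.start}")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.uniprot_ac}: sequence length {len(self.sequence)} != "
                f"coordinate span {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_uniprot(self, column: int) -> int:
        """Map a 1-based region position to its UniProt position."""
        if not (1 <= column <= self.length):
            raise IndexError(f"position {column} outside region of length {self.length}")
        return self.start + column - 1


def trim_or_extend(
    region: tuple[int, int],
    full_sequence: str,
    uniprot_ac: str = "?",
    interface_end: str | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    role: str = "idp",
) -> TrimmedRegion:
    """Extend a short region along its parent protein to reach ``min_len``.

    Rules (all 1-based inclusive coordinates):

    * a region already >= ``min_len`` is returned unchanged;
    * terminal regions (touching residue 1 or the protein's last residue)
      can only be extended inward;
    * internal regions are extended toward both ends; when ``interface_end``
      is ``"n"`` or ``"c"``, the interface-forming end receives the larger
      share of the extension (ceil(deficit/2)+1, capped at the deficit);
    * extension never crosses protein bounds — a deficit that cannot be
      absorbed on one side spills to the other;
    * a protein shorter than ``min_len`` is returned in full.
    """
    start, end = region
    n = len(full_sequence)
    if not (1 <= start <= end <= n):
        raise CoordinateError(
            f"{uniprot_ac}: region {start}-{end} outside sequence of length {n}"
        )
    if interface_end not in (None, "none", "n", "c"):
        raise ValueError(f"interface_end must be one of n|c|none, got {interface_end!r}")
    if interface_end == "none":
        interface_end = None

    length = end - start + 1
    if length >= min_len:
        new_start, new_end = start, end
    elif n <= min_len:
        new_start, new_end = 1, n
    else:
        deficit = min_len - length
        head_room = start - 1  # residues available on the N-terminal side
        tail_room = n - end
        if head_room == 0:  # N-terminal segment: extend toward C only
            want_n, want_c = 0, deficit
        elif tail_room == 0:  # C-terminal segment: extend toward N only
            want_n, want_c = deficit, 0
        elif interface_end == "n":
            want_n = min(deficit, math.ceil(deficit / 2) + 1)
            want_c = deficit - want_n
        elif interface_end == "c":
            want_c = min(deficit, math.ceil(deficit / 2) + 1)
            want_n = deficit - want_c
        else:
            want_n = deficit // 2
            want_c = deficit - want_n
        # clamp to bounds, spilling the remainder to the other side
        add_n = min(want_n, head_room)
        add_c = min(want_c, tail_room)
        remaining = deficit - add_n - add_c
        if remaining > 0:
            spill_n = min(remaining, head_room - add_n)
            add_n += spill_n
            add_c += min(remaining - spill_n, tail_room - add_c)
        new_start, new_end = start - add_n, end + add_c

    return TrimmedRegion(
        uniprot_ac=uniprot_ac,
        start=new_start,
        end=new_end,
        sequence=full_sequence[new_start - 1 : new_end],
        role=role,
        extension_added=(start - new_start, new_end - end),
    )


def pfam_gate(n_sequences: int, threshold: int = DEFAULT_PFAM_THRESHOLD) -> bool:
    """True (include) iff the family's full alignment has >= ``threshold``
    sequences; a count strictly below the threshold excludes the complex."""
    if n_sequences < 0:
        raise ValueError("sequence count cannot be negative")
    return n_sequences >= threshold


# ---------------------------------------------------------------------------
# paired-alignment construction
# ---------------------------------------------------------------------------

DEFAULT_SPECIES_REGEX = r"_([^_]+)$"  # token after the last underscore


def species_of(header: str, header_regex: str = DEFAULT_SPECIES_REGEX) -> str:
    """Extract a species identifier from a FASTA/Stockholm row id."""
    m = re.search(header_regex, header)
    if m:
        return m.group(1) if m.groups() else m.group(0)
    return header


def percent_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fractional identity between two encoded aligned rows.

    Matches are counted over positions where both rows are non-gap; the
    denominator is the shorter ungapped length. Two all-gap rows score 0.
    """
    both = (a != GAP_STATE) & (b != GAP_STATE)
    denom = min(int((a != GAP_STATE).sum()), int((b != GAP_STATE).sum()))
    if denom == 0:
        return 0.0
    matches = int(((a == b) & both).sum())
    return matches / denom


def read_msa(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read an MSA (FASTA or Stockholm, sniffed by default) as (id, row) pairs."""
    path = Path(path)
    if fmt is None:
        head = path.read_text()[:16]
        fmt = "stockholm" if head.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq)) for rec in aln]


def build_paired_alignment(
    msa_a: list[tuple[str, str]],
    msa_b: list[tuple[str, str]],
    query_a: str,
    query_b: str,
    header_regex: str = DEFAULT_SPECIES_REGEX,
) -> PairedAlignment:
    """Concatenate per-species closest homologs of protein A and protein B.

    For each species present in *both* MSAs, the member of each MSA with the
    highest percent identity to its query row is chosen (ties broken by file
    order); species present in only one MSA are dropped. Row ids give the
    species via ``header_regex``. The query species' row comes first.
    """

    def index(msa: list[tuple[str, str]], query: str):
        ids = [sid for sid, _ in msa]
        if query not in ids:
            raise ValueError(f"query {query!r} not found in MSA (ids: {ids[:5]}...)")
        enc = [encode(seq) for _, seq in msa]
        widths = {len(e) for e in enc}
        if len(widths) != 1:
            raise ValueError("MSA rows have unequal lengths")
        qrow = enc[ids.index(query)]
        by_species: dict[str, list[int]] = {}
        for i, sid in enumerate(ids):
            by_species.setdefault(species_of(sid, header_regex), []).append(i)
        return ids, enc, qrow, by_species

    ids_a, enc_a, qa, spec_a = index(msa_a, query_a)
    ids_b, enc_b, qb, spec_b = index(msa_b, query_b)
    qs_a = species_of(query_a, header_regex)
    qs_b = species_of(query_b, header_regex)

    shared = sorted(set(spec_a) & set(spec_b))
    rows: list[tuple[str, str]] = []
    query_row = None
    for sp in shared:
        best_a = max(spec_a[sp], key=lambda i: (percent_identity(enc_a[i], qa), -i))
        best_b = max(spec_b[sp], key=lambda i: (percent_identity(enc_b[i], qb), -i))
        seq = "".join([msa_a[best_a][1], msa_b[best_b][1]])
        rows.append((sp, seq))
        if sp == qs_a == qs_b:
            query_row = sp
    if not rows:
        raise ValueError("no species shared between the two MSAs")
    rows.sort(key=lambda r: (r[0] != query_row, r[0]))
    boundary = len(msa_a[0][1])
    return PairedAlignment.from_sequences(rows, boundary=boundary, query_index=0)


def sequence_weights(
    aln: PairedAlignment, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> np.ndarray:
    """Redundancy weights: w_r = 1 / |{rows with identity >= threshold to r}|.

    The neighbourhood count includes the row itself, so weights lie in
    (0, 1] and the effective sample size is sum(w).
    """
    X = aln.matrix
    n = X.shape[0]
    nongap = X != GAP_STATE
    ungapped = nongap.sum(axis=1).astype(float)  # per-row ungapped length
    counts = np.zeros(n)
    # O(n^2 L) via vectorized row-vs-all comparisons; fine for n up to ~5e3
    for r in range(n):
        both = nongap[r] & nongap
        matches = ((X == X[r]) & both).sum(axis=1)
        denom = np.minimum(ungapped[r], ungapped)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(denom > 0, matches / denom, 0.0)
        counts[r] = (ident >= identity_threshold).sum()
    counts = np.maximum(counts, 1.0)  # guard: an all-gap row matches nothing
    return 1.0 / counts
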