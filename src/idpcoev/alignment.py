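"""Paired-alignment container and FASTA I/O.

A paired alignment concatenates, per species, the closest homolog of protein A
(the IDP) and of protein B (the folded partner): one row per species, with a
boundary column index separating the two proteins and per-row weights that
down-weight redundant sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import decode, encode


@dataclass
class PairedAlignment:
    """Concatenated two-protein alignment keyed by species.

    Attributes
    ----------
    species : list of str
        One identifier per row.
    matrix : (n_rows, n_cols) int8 array
        Encoded states (20 amino acids + gap).
    boundary : int
        Number of columns belonging to protein A; columns ``boundary:`` are
        protein B. 0 < boundary < n_cols.
    weights : (n_rows,) float array or None
        Per-row weights in (0, 1]; None until computed.
    query_index : int
        Row holding the query pair (default 0).
    """

    species: list[str]
    matrix: np.ndarray
    boundary: int
    weights: np.ndarray | None = None
    query_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if not (0 < self.boundary < self.matrix.shape[1]):
            raise ValueError(
                f"boundary {self.boundary} outside (0, {self.matrix.shape[1]})"
            )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.matrix.shape[0],):
                raise ValueError("weights length must match row count")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def effective_n(self) -> float:
        if self.weights is None:
            return float(self.n_rows)
        return float(self.weights.sum())

    def row_sequence(self, r: int) -> str:
        return decode(self.matrix[r])

    @classmethod
    def from_sequences(
        cls,
        records: list[tuple[str, str]],
        boundary: int,
        weights: np.ndarray | None = None,
        query_index: int = 0,
    ) -> "PairedAlignment":
        species = [sid for sid, _ in records]
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        matrix = np.stack([encode(s) for _, s in records])
        return cls(species, matrix, boundary, weights, query_index)

    def gap_fraction(self) -> np.ndarray:
        """Per-column gap fraction (unweighted)."""
        from .alphabet import GAP_STATE

        return (self.matrix == GAP_STATE).mean(axis=0)

    # ---- persistence ------------------------------------------------------

    def write(self, fasta_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write aligned FASTA plus a JSON sidecar {boundary, weights, query_index}."""
        fasta_path = Path(fasta_path)
        with open(fasta_path, "w") as fh:
            for sid, row in zip(self.species, self.matrix):
                fh.write(f">{sid}\n{decode(row)}\n")
        if sidecar_path is None:
            sidecar_path = fasta_path.with_suffix(fasta_path.suffix + ".json")
        meta = {
            "boundary": int(self.boundary),
            "weights": None if self.weights is None else self.weights.tolist(),
            "query_index": int(self.query_index),
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, fasta_path: str | Path, sidecar_path: str | Path | None = None,
             boundary: int | None = None) -> "PairedAlignment":
        fasta_path = Path(fasta_path)
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
        if sidecar_path is None:
            cand = fasta_path.with_suffix(fasta_path.suffix + ".json")
            sidecar_path = cand if cand.exists() else None
        weights = None
        query_index = 0
        if sidecar_path is not None:
            meta = json.loads(Path(sidecar_path).read_text())
            boundary = meta["boundary"]
            if meta.get("weights") is not None:
                weights = np.asarray(meta["weights"], dtype=float)
            query_index = meta.get("query_index", 0)
        if boundary is None:
            raise ValueError("boundary required (sidecar missing and none given)")
        return cls.from_sequences(records, boundary, weights, query_index)
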