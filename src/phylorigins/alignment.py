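"""Gapped nucleotide alignments: parsing, validation, filtering, composition.

The container is a thin numpy-backed class rather than a biopython
``MultipleSeqAlignment`` because the downstream operations (column filters,
pairwise identity, column bootstrap) are all column-wise and benefit from a
contiguous byte matrix.  FASTA parsing itself goes through ``Bio.SeqIO``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from phylorigins.errors import AlignmentError, EmptyResultError, ValidationError

# IUPAC nucleotide codes, 'U' (treated as 'T' in every computation, preserved
# verbatim on output) and the alignment gap.
IUPAC_CHARS = frozenset(b"ACGTURYSWKMBDHVN-")
UNAMBIGUOUS = frozenset(b"ACGTU")
GAP = ord("-")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the two-pass alignment filter.

    ``min_seq_nucleotides``: a sequence is kept only if it has at least this
    many non-gap characters (default 750).  ``min_column_nucleotides``: a
    column is kept only if, over the retained sequences, it has at least this
    many non-gap characters (default 100).  "Fewer than" is strict in both
    cases.  Ambiguity codes, including ``N``, count as present nucleotides:
    RDP-style alignments treat them as data, and the filters are about
    sequence content versus alignment gaps.
    """

    min_seq_nucleotides: int = 750
    min_column_nucleotides: int = 100

    def __post_init__(self) -> None:
        if self.min_seq_nucleotides <= 0 or self.min_column_nucleotides <= 0:
            raise ValidationError("filter thresholds must be strictly positive")


class Alignment:
    """An ordered, gapped, equal-length nucleotide sequence set.

    Residues are stored uppercase as a ``(n_sequences, n_columns)`` uint8
    matrix of ASCII codes; ids are unique and order-preserving.
    """

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        self.ids: list[str] = list(ids)
        self.matrix: np.ndarray = np.ascontiguousarray(matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError("number of ids does not match matrix rows")
        if self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must have at least one column")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if any(not i for i in self.ids):
            raise AlignmentError("empty sequence id")
        self._index = {taxon: row for row, taxon in enumerate(self.ids)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids: list[str] = []
        rows: list[np.ndarray] = []
        n_columns = None
        for taxon, residues in records:
            seq = residues.upper()
            row = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            bad = set(row.tobytes()) - set(IUPAC_CHARS)
            if bad:
                chars = ", ".join(repr(chr(c)) for c in sorted(bad))
                raise AlignmentError(f"sequence {taxon!r}: invalid characters {chars}")
            if n_columns is None:
                n_columns = row.size
            elif row.size != n_columns:
                raise AlignmentError(
                    f"sequence {taxon!r} has length {row.size}, expected {n_columns}"
                )
            ids.append(taxon)
            rows.append(row)
        if not ids:
            raise ValidationError("no sequences found")
        return cls(ids, np.vstack(rows))

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.n_sequences

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def sequence(self, taxon: str) -> str:
        return self.matrix[self._index[taxon]].tobytes().decode("ascii")

    def items(self) -> Iterable[tuple[str, str]]:
        for taxon in self.ids:
            yield taxon, self.sequence(taxon)

    # -- views -------------------------------------------------------------

    def comp_matrix(self) -> np.ndarray:
        """Residue matrix for computations: 'U' mapped to 'T'."""
        out = self.matrix.copy()
        out[out == ord("U")] = ord("T")
        return out

    def nongap_mask(self) -> np.ndarray:
        return self.matrix != GAP

    def subset_taxa(self, keep: Iterable[str]) -> "Alignment":
        """Restrict to ``keep`` (alignment row order preserved)."""
        keep = set(keep)
        missing = keep - set(self.ids)
        if missing:
            raise ValidationError(f"unknown taxa: {sorted(missing)}")
        rows = [r for r, taxon in enumerate(self.ids) if taxon in keep]
        if not rows:
            raise EmptyResultError("taxon subset is empty")
        return Alignment([self.ids[r] for r in rows], self.matrix[rows])

    def take_columns(self, columns: np.ndarray) -> "Alignment":
        columns = np.asarray(columns)
        if columns.size == 0:
            raise EmptyResultError("no columns selected")
        return Alignment(self.ids, self.matrix[:, columns])


def read_fasta(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment, preserving input order.

    Raises an :class:`AlignmentError` for unequal lengths, duplicate ids or
    invalid characters, and a :class:`ValidationError` for an empty file.
    """
    path = Path(path)
    with path.open() as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path_or_handle, width: int = 80) -> None:
    """Write the alignment as FASTA with fixed line wrapping."""
    own = isinstance(path_or_handle, (str, Path))
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        for taxon, residues in aln.items():
            handle.write(f">{taxon}\n")
            for start in range(0, len(residues), width):
                handle.write(residues[start : start + width] + "\n")
    finally:
        if own:
            handle.close()


def fasta_string(aln: Alignment, width: int = 80) -> str:
    buf = io.StringIO()
    write_fasta(aln, buf, width=width)
    return buf.getvalue()


def filter_alignment(aln: Alignment, params: FilterParams | None = None) -> Alignment:
    """Two-pass filter: short sequences first, then sparse columns.

    Pass 1 removes sequences with fewer than ``min_seq_nucleotides`` non-gap
    characters; pass 2 then removes columns with fewer than
    ``min_column_nucleotides`` non-gap characters counted over the retained
    sequences.  The column pass runs once (not iterated to a fixed point).
    """
    params = params or FilterParams()
    nongap = aln.nongap_mask()
    seq_keep = nongap.sum(axis=1) >= params.min_seq_nucleotides
    if not seq_keep.any():
        raise EmptyResultError("sequence filter removed every sequence")
    kept_ids = [taxon for taxon, k in zip(aln.ids, seq_keep) if k]
    matrix = aln.matrix[seq_keep]
    col_keep = (matrix != GAP).sum(axis=0) >= params.min_column_nucleotides
    if not col_keep.any():
        raise EmptyResultError("column filter removed every column")
    return Alignment(kept_ids, matrix[:, col_keep])


def deduplicate(aln: Alignment) -> tuple[Alignment, dict[str, str]]:
    """Keep the first occurrence of each identical residue string.

    Returns the deduplicated alignment plus a mapping duplicate-id → kept-id.
    Equality is exact on the full gapped string ('U' and 'T' are distinct
    here; only literal copies are removed).
    """
    seen: dict[bytes, str] = {}
    keep_rows: list[int] = []
    dup_map: dict[str, str] = {}
    for row, taxon in enumerate(aln.ids):
        key = aln.matrix[row].tobytes()
        if key in seen:
            dup_map[taxon] = seen[key]
        else:
            seen[key] = taxon
            keep_rows.append(row)
    return Alignment([aln.ids[r] for r in keep_rows], aln.matrix[keep_rows]), dup_map


def at_content(residues: str) -> float:
    """Percent A+T among unambiguous bases.

    Counts A, T and U in the numerator and A, C, G, T, U in the denominator;
    gaps, N and the other ambiguity codes contribute to neither.
    """
    seq = residues.upper()
    denom = sum(1 for c in seq if c in "ACGTU")
    if denom == 0:
        raise ValidationError("no unambiguous bases: AT content undefined")
    num = sum(1 for c in seq if c in "ATU")
    return 100.0 * num / denom


def nongap_counts(aln: Alignment) -> Mapping[str, int]:
    counts = aln.nongap_mask().sum(axis=1)
    return dict(zip(aln.ids, (int(c) for c in counts)))
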