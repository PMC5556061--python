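"""Column-level analysis of protein multiple sequence alignments.

Maps reference residue numbers to alignment columns, profiles column
composition and filters records by the residue present at a column
(e.g. counting domains with an acidic residue at a reference position).
'.' and '-' are both gaps; lowercase (insert-state) columns are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

GAP_CHARS = frozenset(".-")


class MsaError(ValueError):
    pass


@dataclass
class Alignment:
    records: "dict[str, str]"  # id -> aligned sequence (uppercased)

    def __post_init__(self) -> None:
        if not self.records:
            raise MsaError("alignment must contain at least one record")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise MsaError(f"ragged alignment: lengths {sorted(lengths)}")
        self.records = {
            rid: seq.upper().replace(".", "-")
            for rid, seq in self.records.items()
        }

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def n_records(self) -> int:
        return len(self.records)

    @classmethod
    def read(cls, path, fmt: Optional[str] = None) -> "Alignment":
        """Read aligned FASTA or Stockholm (auto-detected by default)."""
        from Bio import AlignIO

        if fmt is None:
            head = Path(path).read_text()[:32]
            fmt = "stockholm" if head.startswith("# STOCKHOLM") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        records = {}
        for rec in aln:
            if rec.id in records:
                raise MsaError(f"duplicate record id {rec.id!r}")
            records[rec.id] = str(rec.seq)
        return cls(records=records)

    def write_fasta(self, path) -> None:
        lines = []
        for rid, seq in self.records.items():
            lines.append(f">{rid}")
            lines.append(seq)
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ColumnProfile:
    column: int
    counts: Dict[str, int]
    gap_count: int
    n_records: int

    def percent(self, residues: str, of_non_gap: bool = False) -> float:
        hits = sum(self.counts.get(r, 0) for r in residues)
        denom = (self.n_records - self.gap_count) if of_non_gap else self.n_records
        if denom == 0:
            return 0.0
        return 100.0 * hits / denom


def map_column(
    alignment: Alignment,
    reference_id: str,
    reference_residue_number: int,
    numbering_offset: int = 0,
) -> int:
    """0-based alignment column holding the reference's numbered residue.

    ``numbering_offset`` shifts author numbering: ungapped index =
    reference_residue_number - numbering_offset - 1.
    """
    if reference_id not in alignment.records:
        raise MsaError(f"reference {reference_id!r} not in alignment")
    seq = alignment.records[reference_id]
    target = reference_residue_number - numbering_offset - 1
    if target < 0:
        raise MsaError(f"residue number {reference_residue_number} out of range")
    ungapped = -1
    for col, char in enumerate(seq):
        if char not in GAP_CHARS:
            ungapped += 1
            if ungapped == target:
                return col
    raise MsaError(
        f"residue number {reference_residue_number} beyond reference length "
        f"({ungapped + 1} residues)"
    )


def column_frequencies(alignment: Alignment, column: int) -> ColumnProfile:
    """Exact residue counts (gaps included) for one column."""
    if not 0 <= column < alignment.length:
        raise MsaError(f"column {column} out of range 0..{alignment.length - 1}")
    counts: Dict[str, int] = {}
    gaps = 0
    for seq in alignment.records.values():
        char = seq[column]
        if char in GAP_CHARS:
            gaps += 1
        else:
            counts[char] = counts.get(char, 0) + 1
    return ColumnProfile(
        column=column, counts=counts, gap_count=gaps,
        n_records=alignment.n_records,
    )


def select_by_column(
    alignment: Alignment,
    column: int,
    allowed,
    unique: bool = False,
) -> Tuple[Alignment, int]:
    """Sub-alignment of records whose residue at ``column`` is allowed.

    With ``unique`` the count collapses records with identical aligned
    sequences.  Returns (sub-alignment-or-None, count); count 0 yields
    ``(None, 0)``.
    """
    if not 0 <= column < alignment.length:
        raise MsaError(f"column {column} out of range")
    allowed = frozenset(str(a).upper() for a in allowed)
    chosen = {
        rid: seq
        for rid, seq in alignment.records.items()
        if seq[column] in allowed
    }
    if unique:
        count = len(set(chosen.values()))
    else:
        count = len(chosen)
    if not chosen:
        return None, 0
    return Alignment(records=chosen), count


def position_probability_matrix(
    sequences: Sequence[str],
) -> List[Dict[str, float]]:
    """Per-column residue probabilities (gaps excluded from normalisation)."""
    if not sequences:
        raise MsaError("need at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise MsaError("sequences must have equal length")
    length = lengths.pop()
    matrix: List[Dict[str, float]] = []
    for col in range(length):
        counts: Dict[str, int] = {}
        for seq in sequences:
            char = seq[col].upper()
            if char in GAP_CHARS:
                continue
            counts[char] = counts.get(char, 0) + 1
        total = sum(counts.values())
        matrix.append(
            {r: c / total for r, c in counts.items()} if total else {}
        )
    return matrix


def write_ppm_tsv(matrix: Sequence[Mapping[str, float]], path) -> None:
    residues = sorted({r for col in matrix for r in col})
    lines = ["position\t" + "\t".join(residues)]
    for i, col in enumerate(matrix):
        lines.append(
            str(i) + "\t" + "\t".join(f"{col.get(r, 0.0):.6g}" for r in residues)
        )
    Path(path).write_text("\n".join(lines) + "\n")
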