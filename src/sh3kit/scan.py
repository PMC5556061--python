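"""Proteome scanning for motif hits and candidate ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from sh3kit.motif import (
    CORE_LENGTH,
    MotifError,
    MotifMatch,
    MotifPattern,
    PositionFrequencyMatrix,
    match_sequence,
)

logger = logging.getLogger(__name__)

_NUCLEOTIDE = frozenset("ACGTU")

FLANK_LENGTH = 6  # residues N-terminal of the window inspected for D/E


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class ScanHit:
    record_id: str
    start: int  # 1-based position of the -1 residue
    window: str
    score: Optional[float] = None
    flank_acidity: int = 0

    @property
    def end(self) -> int:
        return self.start + CORE_LENGTH - 1


def _check_protein(record: SequenceRecord) -> None:
    letters = set(record.sequence.upper())
    if letters and letters <= _NUCLEOTIDE:
        raise ScanError(
            f"record {record.id!r} looks like a nucleotide sequence; "
            "protein input required"
        )


def _flank_acidity(sequence: str, start_1based: int) -> int:
    lo = max(0, start_1based - 1 - FLANK_LENGTH)
    flank = sequence[lo : start_1based - 1]
    return sum(1 for r in flank if r in "DE")


def scan_proteome(
    records: Sequence[SequenceRecord],
    pattern: Optional[MotifPattern] = None,
    pfm: Optional[PositionFrequencyMatrix] = None,
) -> List[ScanHit]:
    """All motif hits across records, in record order then by start."""
    pattern = pattern or MotifPattern.default()
    seen: set = set()
    hits: List[ScanHit] = []
    for rec in records:
        if rec.id in seen:
            raise ScanError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        _check_protein(rec)
        seq = rec.sequence.upper()
        if len(seq) < CORE_LENGTH:
            logger.warning("record %r shorter than %d residues; skipped",
                           rec.id, CORE_LENGTH)
            continue
        for m in match_sequence(rec.id, seq, pattern=pattern, pfm=pfm):
            hits.append(
                ScanHit(
                    record_id=m.sequence_id,
                    start=m.start,
                    window=m.window,
                    score=m.score,
                    flank_acidity=_flank_acidity(seq, m.start),
                )
            )
    return hits


def rank_hits(
    hits: Sequence[ScanHit], weights: Optional[Mapping[str, float]] = None
) -> List[ScanHit]:
    """Stable sort by weighted (score, flank_acidity), descending.

    Ties resolve by record_id then start.
    """
    weights = dict(weights or {"score": 1.0, "flank_acidity": 0.0})
    w_score = float(weights.get("score", 0.0))
    w_acid = float(weights.get("flank_acidity", 0.0))
    if w_score != 0.0 and any(h.score is None for h in hits):
        raise ScanError("hits must carry scores when the score weight is non-zero")

    def key(h: ScanHit):
        weighted = w_score * (h.score or 0.0) + w_acid * h.flank_acidity
        return (-weighted, h.record_id, h.start)

    return sorted(hits, key=key)


TSV_COLUMNS = ("record_id", "start", "end", "window", "score", "flank_acidity")


def write_hits_tsv(hits: Sequence[ScanHit], path) -> None:
    lines = ["\t".join(TSV_COLUMNS)]
    for h in hits:
        score = "" if h.score is None else f"{h.score:.6g}"
        lines.append(
            f"{h.record_id}\t{h.start}\t{h.end}\t{h.window}\t{score}\t{h.flank_acidity}"
        )
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise ScanError(f"cannot write hits to {path}: {exc}") from exc


def read_hits_tsv(path) -> List[ScanHit]:
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise ScanError(f"cannot read hits from {path}: {exc}") from exc
    if not lines or lines[0].split("\t") != list(TSV_COLUMNS):
        raise ScanError(f"{path} is not a hits TSV")
    hits = []
    for line in lines[1:]:
        rec_id, start, _end, window, score, acidity = line.split("\t")
        hits.append(
            ScanHit(
                record_id=rec_id,
                start=int(start),
                window=window,
                score=float(score) if score else None,
                flank_acidity=int(acidity),
            )
        )
    return hits


def read_fasta(path) -> List[SequenceRecord]:
    """Multi-record protein FASTA (wrapped or unwrapped, any case)."""
    from Bio import SeqIO

    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    description=rec.description,
                )
            )
    except (OSError, ValueError) as exc:
        raise ScanError(f"unreadable FASTA {path} at record {len(records)}: {exc}")
    return records
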