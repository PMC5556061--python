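"""Consensus-motif model for SH3 polyproline ligands.

The ligand core is an eight-position window labelled -1, 0, +1 ... +6
relative to the first conserved proline (position 0).  The default
pattern encodes (A/P)(-1) P(0) x(+1) K(+2) P(+3) x(+4) (L/R)(+5) Z(+6)
with Z = {L, P, S, T}.  A position-frequency matrix built from aligned
peptide cores provides log-odds (bit) scores for ranking windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_VALID_PEPTIDE = _AA_SET | {"X"}

CORE_LENGTH = 8
POSITION_LABELS: Tuple[str, ...] = ("-1", "0", "+1", "+2", "+3", "+4", "+5", "+6")


class MotifError(ValueError):
    """Invalid input to a motif operation."""


class MotifConfigError(MotifError):
    """Inconsistent motif/PFM configuration (e.g. zero probabilities)."""


def _validate_sequence(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise MotifError(f"{what} must be non-empty")
    seq = seq.upper()
    bad = set(seq) - _VALID_PEPTIDE
    if bad:
        raise MotifError(
            f"{what} contains invalid residue characters: {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A short peptide with an identifier.

    ``sequence`` is upper-case one-letter code; ``X`` denotes an unknown
    residue and never satisfies any motif position.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """Per-position sets of permitted residues for the 8-residue core.

    ``allowed[p]`` of ``None`` means the position is unconstrained
    (any of the 20 standard residues; ``X`` is still rejected).
    """

    allowed: Tuple[Optional[frozenset], ...]

    def __post_init__(self) -> None:
        if len(self.allowed) != CORE_LENGTH:
            raise MotifError(f"pattern must have {CORE_LENGTH} positions")

    def matches(self, window: str) -> bool:
        """True when an 8-residue window satisfies every position."""
        if len(window) != CORE_LENGTH:
            return False
        for res, allowed in zip(window, self.allowed):
            if res == "X":
                return False
            if res not in _AA_SET:
                raise MotifError(f"invalid residue character {res!r} in window")
            if allowed is not None and res not in allowed:
                return False
        return True

    @classmethod
    def default(cls) -> "MotifPattern":
        """The strict high-affinity consensus pattern."""
        return cls(
            allowed=(
                frozenset("AP"),    # -1
                frozenset("P"),     # 0
                None,               # +1
                frozenset("K"),     # +2
                frozenset("P"),     # +3
                None,               # +4
                frozenset("LR"),    # +5
                frozenset("LPST"),  # +6  (Z)
            )
        )

    @classmethod
    def relaxed(cls) -> "MotifPattern":
        """Relaxed variant: R also accepted at +2, no +6 constraint."""
        return cls(
            allowed=(
                frozenset("AP"),
                frozenset("P"),
                None,
                frozenset("KR"),
                frozenset("P"),
                None,
                frozenset("LR"),
                None,
            )
        )


@dataclass(frozen=True)
class AlignedPeptideSet:
    """Peptides with the 0-based offset of the core's -1 position."""

    peptides: Tuple[Peptide, ...]
    core_offsets: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.peptides:
            raise MotifError("aligned peptide set must not be empty")
        if len(self.peptides) != len(self.core_offsets):
            raise MotifError("peptides and core_offsets must align")
        for pep, off in zip(self.peptides, self.core_offsets):
            if off < 0 or off + CORE_LENGTH > len(pep):
                raise MotifError(
                    f"core offset {off} does not admit an 8-residue window "
                    f"in peptide {pep.id!r}"
                )

    def cores(self) -> List[str]:
        return [
            pep.sequence[off : off + CORE_LENGTH]
            for pep, off in zip(self.peptides, self.core_offsets)
        ]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue probabilities for the 8-position core."""

    probs: Tuple[Mapping[str, float], ...]
    pseudocount: float
    n_sequences: int
    positions: Tuple[str, ...] = POSITION_LABELS

    def __post_init__(self) -> None:
        if len(self.probs) != CORE_LENGTH:
            raise MotifError("PFM must cover 8 positions")
        for i, col in enumerate(self.probs):
            total = sum(col.values())
            if abs(total - 1.0) > 1e-9:
                raise MotifError(f"PFM column {self.positions[i]} sums to {total}")
            if any(p < 0 for p in col.values()):
                raise MotifError("PFM probabilities must be non-negative")

    def prob(self, position_index: int, residue: str) -> float:
        return self.probs[position_index].get(residue, 0.0)

    def to_tsv(self, path) -> None:
        """Write positions-as-rows, residues-as-columns matrix."""
        lines = ["position\t" + "\t".join(AMINO_ACIDS)]
        for label, col in zip(self.positions, self.probs):
            lines.append(
                label + "\t" + "\t".join(f"{col.get(a, 0.0):.6g}" for a in AMINO_ACIDS)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path, pseudocount: float = 0.0, n_sequences: int = 0):
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].split("\t")[1:]
        probs = []
        for line in lines[1:]:
            fields = line.split("\t")
            col = {a: float(v) for a, v in zip(header, fields[1:])}
            # renormalise against round-off from text formatting
            total = sum(col.values())
            probs.append({a: v / total for a, v in col.items()})
        return cls(probs=tuple(probs), pseudocount=pseudocount, n_sequences=n_sequences)


@dataclass(frozen=True)
class MotifMatch:
    """A pattern-satisfying window in a sequence.

    ``start`` is 1-based and points at the -1 residue of the core.
    """

    sequence_id: str
    start: int
    window: str
    score: Optional[float] = None

    @property
    def end(self) -> int:
        return self.start + CORE_LENGTH - 1


def locate_core(peptide: Peptide, pattern: Optional[MotifPattern] = None) -> List[int]:
    """All 0-based offsets at which the peptide carries a core window."""
    pattern = pattern or MotifPattern.default()
    seq = peptide.sequence
    return [
        off
        for off in range(len(seq) - CORE_LENGTH + 1)
        if pattern.matches(seq[off : off + CORE_LENGTH])
    ]


def anchor_peptides(
    peptides: Sequence[Peptide],
    pattern: Optional[MotifPattern] = None,
    pseudocount: float = 0.5,
) -> AlignedPeptideSet:
    """Anchor each peptide on its motif core for PFM construction.

    Two-pass rule: peptides with a unique core define a bootstrap PFM;
    peptides with several candidate cores take the highest-scoring one
    under that bootstrap (ties broken leftmost).  Peptides without any
    core are rejected.
    """
    pattern = pattern or MotifPattern.default()
    hits = []
    for pep in peptides:
        offs = locate_core(pep, pattern)
        if not offs:
            raise MotifError(f"peptide {pep.id!r} has no motif core")
        hits.append(offs)

    unambiguous = [
        (pep, offs[0]) for pep, offs in zip(peptides, hits) if len(offs) == 1
    ]
    bootstrap: Optional[PositionFrequencyMatrix] = None
    if unambiguous and any(len(o) > 1 for o in hits):
        bootstrap = build_pfm(
            AlignedPeptideSet(
                peptides=tuple(p for p, _ in unambiguous),
                core_offsets=tuple(o for _, o in unambiguous),
            ),
            pseudocount=max(pseudocount, 1e-6),
        )

    offsets: List[int] = []
    for pep, offs in zip(peptides, hits):
        if len(offs) == 1 or bootstrap is None:
            offsets.append(offs[0])
        else:
            scored = [
                (-score_window(pep.sequence[o : o + CORE_LENGTH], bootstrap), o)
                for o in offs
            ]
            scored.sort()
            offsets.append(scored[0][1])
    return AlignedPeptideSet(peptides=tuple(peptides), core_offsets=tuple(offsets))


def build_pfm(
    aligned: AlignedPeptideSet, pseudocount: float = 0.5
) -> PositionFrequencyMatrix:
    """Position frequency matrix from anchored peptide cores.

    probs[p][r] = (count(r at p) + pseudocount) / (n + 20 * pseudocount)
    """
    if not aligned.peptides:
        raise MotifError("cannot build a PFM from an empty peptide set")
    if pseudocount < 0:
        raise MotifError("pseudocount must be non-negative")
    n = len(aligned.peptides)
    denom = n + 20.0 * pseudocount
    cores = aligned.cores()
    probs = []
    for p in range(CORE_LENGTH):
        counts = {a: 0 for a in AMINO_ACIDS}
        for core in cores:
            res = core[p]
            if res == "X":
                raise MotifError("anchored cores must not contain X")
            counts[res] += 1
        probs.append({a: (c + pseudocount) / denom for a, c in counts.items()})
    return PositionFrequencyMatrix(
        probs=tuple(probs), pseudocount=pseudocount, n_sequences=n
    )


def uniform_background() -> Dict[str, float]:
    return {a: 1.0 / 20.0 for a in AMINO_ACIDS}


def score_window(
    window: str,
    pfm: PositionFrequencyMatrix,
    background: Optional[Mapping[str, float]] = None,
) -> float:
    """Log-odds score in bits: sum_p log2(probs[p][w_p] / background[w_p])."""
    window = _validate_sequence(window, "window")
    if len(window) != CORE_LENGTH:
        raise MotifError(f"window must be {CORE_LENGTH} residues, got {len(window)}")
    if "X" in window:
        raise MotifError("cannot score a window containing X")
    background = background or uniform_background()
    total = sum(background.values())
    if abs(total - 1.0) > 1e-6 or any(b <= 0 for b in background.values()):
        raise MotifConfigError("background must be strictly positive and sum to 1")
    score = 0.0
    for p, res in enumerate(window):
        prob = pfm.prob(p, res)
        if prob <= 0.0:
            raise MotifConfigError(
                "PFM probability is zero; rebuild with pseudocount > 0 for scoring"
            )
        score += math.log2(prob / background[res])
    return score


def match_sequence(
    sequence_id: str,
    sequence: str,
    pattern: Optional[MotifPattern] = None,
    pfm: Optional[PositionFrequencyMatrix] = None,
    background: Optional[Mapping[str, float]] = None,
) -> List[MotifMatch]:
    """Every pattern-satisfying window, overlaps included, sorted by start.

    Starts are 1-based and refer to the -1 residue of the core.
    """
    pattern = pattern or MotifPattern.default()
    seq = _validate_sequence(sequence)
    matches = []
    for off in range(len(seq) - CORE_LENGTH + 1):
        window = seq[off : off + CORE_LENGTH]
        if "X" in window:
            continue
        if pattern.matches(window):
            score = score_window(window, pfm, background) if pfm else None
            matches.append(
                MotifMatch(sequence_id=sequence_id, start=off + 1, window=window,
                           score=score)
            )
    return matches


# ---------------------------------------------------------------------------
# peptide list I/O

def read_peptides(path) -> List[Peptide]:
    """Read peptides from FASTA or one-sequence-per-line text."""
    text = Path(path).read_text()
    peptides: List[Peptide] = []
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            peptides.append(Peptide(id=rec.id, sequence=str(rec.seq)))
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if line:
                peptides.append(Peptide(id=f"pep{i + 1}", sequence=line))
    if not peptides:
        raise MotifError(f"no peptides found in {path}")
    return peptides
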