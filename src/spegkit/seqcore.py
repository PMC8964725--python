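"""Nucleic-acid primitives shared by all modules.

Sequences are plain Python strings over {A,C,G,T} (N allowed only in PAM
patterns), always written 5'->3'. All internal coordinates are 0-based,
half-open. RNA (U) appears only at serialization time via :func:`to_rna`.

Codon-level synonymy uses the standard genetic code (translation table 1);
a stop codon replaced by another stop codon counts as synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import OutOfFrameError, ValidationError

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, *, allow_n: bool = False, allow_empty: bool = False,
                 name: str = "sequence") -> str:
    """Upper-case and validate a DNA string; returns the normalized string."""
    if not isinstance(seq, str):
        raise ValidationError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq and not allow_empty:
        raise ValidationError(f"{name} must be non-empty")
    alphabet = _DNA_N if allow_n else _DNA
    bad = set(seq) - alphabet
    if bad:
        raise ValidationError(f"{name} contains invalid characters: {sorted(bad)}")
    return seq


def complement(seq: str) -> str:
    return validate_dna(seq, allow_n=True, allow_empty=True).translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (involution; length preserved)."""
    return complement(seq)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet mapping (T -> U), used only at output time."""
    return seq.replace("T", "U").replace("t", "u")


def matches_pattern(seq: str, pattern: str) -> bool:
    """True iff `seq` matches `pattern`, where N matches any of A/C/G/T.

    N in `seq` never matches anything (including pattern N).
    """
    if len(seq) != len(pattern):
        return False
    for base, pat in zip(seq.upper(), pattern.upper()):
        if base not in _DNA:
            return False
        if pat != "N" and base != pat:
            return False
    return True


@dataclass(frozen=True, order=True)
class Interval:
    """0-based, half-open reference interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, coord: int) -> bool:
        return self.start <= coord < self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ReadingFrameAnnotation:
    """Reading-frame register of the edited gene relative to the reference.

    `frame_anchor` is the reference coordinate of any codon-position-1 base on
    the coding strand; codon positions cycle 1,2,3 along the coding strand's
    5'->3' direction (decreasing reference coordinate when the coding strand
    is '-').
    """

    coding_strand: str
    frame_anchor: int
    cds_interval: Interval

    def __post_init__(self) -> None:
        if self.coding_strand not in ("+", "-"):
            raise ValidationError("coding_strand must be '+' or '-'")
        if not self.cds_interval.contains(self.frame_anchor):
            raise ValidationError("frame_anchor must lie inside cds_interval")


def codon_position(coord: int, frame: ReadingFrameAnnotation) -> int:
    """Position (1/2/3) of a reference base within its codon on the coding strand."""
    if not frame.cds_interval.contains(coord):
        raise OutOfFrameError(f"coordinate {coord} outside CDS {frame.cds_interval}")
    if frame.coding_strand == "+":
        return (coord - frame.frame_anchor) % 3 + 1
    return (frame.frame_anchor - coord) % 3 + 1


class CodonTable:
    """Total codon -> amino-acid mapping (stop = '*')."""

    def __init__(self, mapping: dict[str, str]):
        if len(mapping) != 64:
            raise ValidationError("codon table must cover all 64 codons")
        self._mapping = dict(mapping)

    @classmethod
    def standard(cls) -> "CodonTable":
        table = _BioCodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(mapping)

    def amino_acid(self, codon: str) -> str:
        codon = validate_dna(codon, name="codon")
        if len(codon) != 3:
            raise ValidationError(f"codon must be a 3-mer, got {codon!r}")
        return self._mapping[codon]


_STANDARD_TABLE: CodonTable | None = None


def standard_table() -> CodonTable:
    global _STANDARD_TABLE
    if _STANDARD_TABLE is None:
        _STANDARD_TABLE = CodonTable.standard()
    return _STANDARD_TABLE


def is_synonymous(codon_a: str, codon_b: str, table: CodonTable | None = None) -> bool:
    """True iff both codons encode the same amino acid (stop == stop)."""
    table = table or standard_table()
    return table.amino_acid(codon_a) == table.amino_acid(codon_b)


def synonymous_alternatives(codon: str, pos: int,
                            table: CodonTable | None = None) -> set[str]:
    """All bases b != codon[pos] whose substitution at `pos` (1-based) is synonymous."""
    table = table or standard_table()
    codon = validate_dna(codon, name="codon")
    if len(codon) != 3:
        raise ValidationError(f"codon must be a 3-mer, got {codon!r}")
    if pos not in (1, 2, 3):
        raise ValidationError("codon position must be 1, 2 or 3")
    out: set[str] = set()
    for base in _DNA:
        if base == codon[pos - 1]:
            continue
        alt = codon[: pos - 1] + base + codon[pos:]
        if is_synonymous(codon, alt, table):
            out.add(base)
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ plumbing


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into [(id, sequence), ...]."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write [(id, sequence), ...] as FASTA wrapped at 60 columns."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a 4-line FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()
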