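"""Amplicon-read alignment, outcome classification and frequency calculation.

Reads are aligned semi-globally (read global, reference local) with an
affine-gap Gotoh kernel, indels are left-normalized, and every read is
classified against the intended edit, the designed same-sense mutations
(SSMs), unintended indels inside the quantification window, and pegRNA
scaffold incorporation at the nick.

Frequency definitions:

* base-substitution frequency per position and type = reads carrying that
  substitution and no indel / total reads covering the position, reported
  only where depth >= 1000 (default);
* intended-indel frequency = reads whose only indel is exactly the designed
  one / reads covering the nick;
* unintended-indel frequency = reads with >= 1 unintended indel inside the
  window spanning 8 nt upstream of the protospacer to 52 nt downstream of
  its 3' end (80 bp for a 20-nt protospacer) / reads aligned across that
  window;
* incomplete products = reads with only SSMs but no intended edit;
  byproducts = reads whose only event is a scaffold-derived insertion.

Stray substitutions (sequencing errors) outside the designed positions do
not contribute to any class flag; they appear only in the per-position
substitution matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._gotoh import semiglobal_align
from .errors import RangeError, UsageError, ValidationError
from .pegdesign import (EditSpec, EditedReference, PegRNADesign, SCAFFOLD_76,
                        TargetSpec)
from .seqcore import Interval, complement, reverse_complement, validate_dna

SUBSTITUTION_TYPES = tuple(f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b)


# ---------------------------------------------------------------------------
# Reference bundle


@dataclass(frozen=True)
class AmpliconReference:
    """Amplicon sequence plus target geometry, intended edit, SSMs, scaffold."""

    target: TargetSpec
    edit: EditSpec | None = None
    ssms: tuple[tuple[int, str, str], ...] = ()
    scaffold: str = SCAFFOLD_76

    def __post_init__(self) -> None:
        if self.edit is not None:
            self.edit.validate_against(self.target)
        if self.scaffold:
            validate_dna(self.scaffold, name="scaffold")
        for pos, ref_b, alt_b in self.ssms:
            if pos < 1:
                raise ValidationError("SSM offsets are positive RTT positions")
            validate_dna(ref_b, name="ssm ref base")
            validate_dna(alt_b, name="ssm alt base")

    @property
    def sequence(self) -> str:
        return self.target.reference

    @property
    def nick_plus(self) -> int:
        """Nick boundary in plus-strand coordinates (insertion coordinate)."""
        return self.target.nick_coord

    @classmethod
    def from_design(cls, target: TargetSpec, edit: EditSpec | None,
                    design: PegRNADesign) -> "AmpliconReference":
        return cls(target, edit, tuple(design.ssms), design.scaffold)

    def intended_events(self) -> tuple[str, int, str, str]:
        """(kind, plus_start, old_plus, new_plus) of the intended edit."""
        if self.edit is None:
            raise UsageError("amplicon reference carries no intended edit")
        eref = EditedReference(self.target, self.edit)
        ref = self.sequence
        b = eref.change_start
        old = ref[b:b + eref.old_len]
        new = eref.sequence[b:b + eref.new_len]
        return self.edit.kind, b, old, new

    def ssm_plus_positions(self) -> tuple[tuple[int, str, str], ...]:
        """SSMs as (plus index on the original reference, ref base, alt base)."""
        out = []
        edit = self.edit
        for pos, ref_b, alt_b in self.ssms:
            orig_offset = pos
            if edit is not None and edit.kind == "insertion" and pos >= edit.offset:
                orig_offset = pos - edit.length
            elif edit is not None and edit.kind == "deletion" and pos >= edit.offset:
                orig_offset = pos + edit.length
            idx = self.target.offset_to_index(orig_offset)
            if self.target.strand == "+":
                out.append((idx, ref_b, alt_b))
            else:
                out.append((idx, complement(ref_b), complement(alt_b)))
        return tuple(out)


def quant_window(ref: AmpliconReference | TargetSpec) -> Interval:
    """8 nt upstream of the protospacer to 52 nt downstream of its 3' end.

    Oriented on the protospacer strand; the PAM lies inside the downstream
    span, and the length is 8 + protospacer length + 52 (80 bp for 20 nt).
    """
    target = ref.target if isinstance(ref, AmpliconReference) else ref
    proto = target.protospacer
    if target.strand == "+":
        window = Interval(proto.start - 8, proto.end + 52)
    else:
        window = Interval(proto.start - 52, proto.end + 8)
    if window.start < 0 or window.end > len(target.reference):
        raise RangeError("quantification window exceeds the amplicon")
    return window


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class ReadAlignment:
    """Events of one read against the amplicon, in plus-strand coordinates."""

    read_id: str
    aligned: bool
    score: int = 0
    substitutions: frozenset[tuple[int, str]] = frozenset()
    insertions: tuple[tuple[int, str], ...] = ()
    deletions: tuple[Interval, ...] = ()
    covered: Interval = field(default_factory=lambda: Interval(0, 0))

    @property
    def has_indel(self) -> bool:
        return bool(self.insertions or self.deletions)


def normalize_insertion(ref: str, pos: int, seq: str,
                        blocked: frozenset[int] = frozenset()) -> tuple[int, str]:
    """Left-shift an insertion through equal flanking bases (VCF-style)."""
    while pos > 0 and ref[pos - 1] == seq[-1] and (pos - 1) not in blocked:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def normalize_deletion(ref: str, start: int, end: int,
                       blocked: frozenset[int] = frozenset()) -> Interval:
    """Left-shift a deletion through equal flanking bases."""
    while start > 0 and ref[start - 1] == ref[end - 1] and (start - 1) not in blocked:
        start -= 1
        end -= 1
    return Interval(start, end)


def trim_read_ends(sequence: str, qualities: Sequence[int],
                   min_quality: int = 30) -> str:
    """Trim bases with Phred quality below `min_quality` from both read ends.

    Stands in for the usual Q30 end-trim of real data; simulated reads have
    constant qualities, so the default pipeline leaves trimming off.
    """
    if len(sequence) != len(qualities):
        raise ValidationError("sequence and qualities differ in length")
    start, end = 0, len(sequence)
    while start < end and qualities[start] < min_quality:
        start += 1
    while end > start and qualities[end - 1] < min_quality:
        end -= 1
    return sequence[start:end]


@dataclass(frozen=True)
class AlignConfig:
    match: int = 2
    mismatch: int = -4
    gap_open: int = 6
    gap_extend: int = 1
    min_read_length: int = 30
    min_score: float = 0.0
    band: int | None = 24


def align_read(read: str | tuple[str, str], ref: AmpliconReference,
               config: AlignConfig | None = None) -> ReadAlignment:
    """Best-scoring semi-global alignment of one read to the amplicon.

    Reads shorter than `min_read_length` or scoring below `min_score` are
    returned with ``aligned=False`` and excluded from all denominators.
    """
    cfg = config or AlignConfig()
    read_id, seq = read if isinstance(read, tuple) else ("read", read)
    seq = validate_dna(seq, name="read")
    refseq = ref.sequence
    if len(seq) < cfg.min_read_length:
        return ReadAlignment(read_id, False)
    score, ref_start, ops = semiglobal_align(
        seq, refseq, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend,
        band=cfg.band)
    if score < cfg.min_score:
        return ReadAlignment(read_id, False, score=int(score))
    subs: set[tuple[int, str]] = set()
    insertions: list[tuple[int, str]] = []
    deletions: list[Interval] = []
    i, j = 0, ref_start
    k = 0
    n_ops = len(ops)
    while k < n_ops:
        op = ops[k]
        if op == 0:
            if seq[i] != refseq[j]:
                subs.add((j, seq[i]))
            i += 1
            j += 1
            k += 1
        elif op == 1:
            start = i
            while k < n_ops and ops[k] == 1:
                i += 1
                k += 1
            insertions.append((j, seq[start:i]))
        else:
            start = j
            while k < n_ops and ops[k] == 2:
                j += 1
                k += 1
            deletions.append(Interval(start, j))
    covered = Interval(ref_start, j)
    blocked = frozenset(p for p, _ in subs)
    insertions = [normalize_insertion(refseq, p, s, blocked) for p, s in insertions]
    deletions = [normalize_deletion(refseq, d.start, d.end, blocked) for d in deletions]
    return ReadAlignment(read_id, True, score=int(score),
                         substitutions=frozenset(subs),
                         insertions=tuple(insertions), deletions=tuple(deletions),
                         covered=covered)


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-read outcome flags."""

    read_id: str
    has_intended_edit: bool
    ssm_flags: tuple[tuple[int, bool], ...]
    has_unintended_indel_in_window: bool
    has_intended_indel_exact: bool
    has_scaffold_incorporation: bool

    @property
    def has_ssm(self) -> bool:
        return any(flag for _, flag in self.ssm_flags)


@dataclass(frozen=True)
class ClassifiedRead:
    alignment: ReadAlignment
    outcome: OutcomeRecord
    covers_window: bool
    covers_edit_locus: bool
    covers_nick: bool


@dataclass(frozen=True)
class ScaffoldDetectorConfig:
    """Thresholds of the scaffold-incorporation detector (all tunable)."""

    min_length: int = 3
    max_mismatches: int = 1
    max_nick_distance: int = 5


def _insertion_placements(ref: str, pos: int, seq: str) -> list[tuple[int, str]]:
    """All score-equivalent placements of an insertion (left and right shifts)."""
    out = [(pos, seq)]
    p, s = pos, seq
    while p > 0 and ref[p - 1] == s[-1]:
        s = ref[p - 1] + s[:-1]
        p -= 1
        out.append((p, s))
    p, s = pos, seq
    while p < len(ref) and ref[p] == s[0]:
        s = s[1:] + ref[p]
        p += 1
        out.append((p, s))
    return out


def _is_scaffold_insertion(ref: AmpliconReference, pos: int, seq: str,
                           cfg: ScaffoldDetectorConfig) -> bool:
    if not ref.scaffold or len(seq) < cfg.min_length:
        return False
    tail_rc = reverse_complement(ref.scaffold)
    for p, s in _insertion_placements(ref.sequence, pos, seq):
        if abs(p - ref.nick_plus) > cfg.max_nick_distance:
            continue
        pam_strand_seq = s if ref.target.strand == "+" else reverse_complement(s)
        expected = tail_rc[:len(s)]
        mism = sum(a != b for a, b in zip(pam_strand_seq, expected))
        if mism <= cfg.max_mismatches:
            return True
    return False


def detect_scaffold_incorporation(aln: ReadAlignment, ref: AmpliconReference,
                                  config: ScaffoldDetectorConfig | None = None) -> bool:
    """True iff some insertion near the nick matches the scaffold 3' end.

    The insertion must be >= 3 nt, lie within 5 nt of the nick (under any
    score-equivalent placement) and match the reverse complement of the
    scaffold's 3'-terminal run of equal length with <= 1 mismatch.
    """
    cfg = config or ScaffoldDetectorConfig()
    return any(_is_scaffold_insertion(ref, pos, seq, cfg)
               for pos, seq in aln.insertions)


def _intended_observed(aln: ReadAlignment, ref: AmpliconReference) -> bool:
    kind, b, old, new = ref.intended_events()
    refseq = ref.sequence
    if kind == "substitution":
        for off, expected in enumerate(new):
            p = b + off
            if any(d.contains(p) for d in aln.deletions):
                return False
            read_base = dict(aln.substitutions).get(p, refseq[p])
            if read_base != expected:
                return False
        return True
    if kind == "insertion":
        want = normalize_insertion(refseq, b, new)
        return want in aln.insertions
    want_del = normalize_deletion(refseq, b, b + len(old))
    return want_del in aln.deletions


def classify_read(aln: ReadAlignment, ref: AmpliconReference,
                  detector: ScaffoldDetectorConfig | None = None) -> ClassifiedRead | None:
    """Set the outcome flags of one aligned read; None for unaligned reads."""
    if not aln.aligned:
        return None
    refseq = ref.sequence
    window = quant_window(ref)
    covers_window = aln.covered.contains_interval(window)
    covers_nick = (aln.covered.start <= ref.nick_plus - 1
                   and ref.nick_plus + 1 <= aln.covered.end)
    sub_by_pos = dict(aln.substitutions)

    intended = False
    intended_ins: tuple[int, str] | None = None
    intended_del: Interval | None = None
    covers_edit = True
    if ref.edit is not None:
        kind, b, old, new = ref.intended_events()
        locus = Interval(b, max(b + len(old), b + 1))
        covers_edit = aln.covered.contains_interval(locus)
        if covers_edit:
            intended = _intended_observed(aln, ref)
        if kind == "insertion":
            intended_ins = normalize_insertion(refseq, b, new)
        elif kind == "deletion":
            intended_del = normalize_deletion(refseq, b, b + len(old))

    ssm_flags = []
    for (pos, _, _), (idx, _, alt_plus) in zip(ref.ssms, ref.ssm_plus_positions()):
        seen = (not any(d.contains(idx) for d in aln.deletions)
                and sub_by_pos.get(idx) == alt_plus
                and aln.covered.contains(idx))
        ssm_flags.append((pos, seen))

    cfg = detector or ScaffoldDetectorConfig()
    scaffold_ins = [ins for ins in aln.insertions
                    if _is_scaffold_insertion(ref, ins[0], ins[1], cfg)]
    has_scaffold = bool(scaffold_ins)

    # an indel counts as in-window if any score-equivalent placement is
    unintended = False
    for pos, seq in aln.insertions:
        if (pos, seq) == intended_ins or (pos, seq) in scaffold_ins:
            continue
        placements = _insertion_placements(refseq, pos, seq)
        if any(window.start <= p <= window.end for p, _ in placements):
            unintended = True
    for dele in aln.deletions:
        if dele == intended_del:
            continue
        a, b = dele.start, dele.end  # rightmost score-equivalent placement
        while b < len(refseq) and refseq[a] == refseq[b]:
            a += 1
            b += 1
        if Interval(dele.start, b).overlaps(window):
            unintended = True

    intended_indel_exact = False
    if ref.edit is not None and ref.edit.kind in ("insertion", "deletion"):
        n_indels = len(aln.insertions) + len(aln.deletions)
        intended_indel_exact = intended and n_indels == 1

    record = OutcomeRecord(
        read_id=aln.read_id,
        has_intended_edit=intended,
        ssm_flags=tuple(ssm_flags),
        has_unintended_indel_in_window=unintended,
        has_intended_indel_exact=intended_indel_exact,
        has_scaffold_incorporation=has_scaffold,
    )
    return ClassifiedRead(aln, record, covers_window, covers_edit, covers_nick)


# ---------------------------------------------------------------------------
# Frequencies


def substitution_frequencies(records: Sequence[ClassifiedRead],
                             ref: AmpliconReference,
                             min_depth: int = 1000) -> pd.DataFrame:
    """Per-position matrix of the 12 substitution frequencies plus depth.

    Numerators count reads carrying the substitution and no indel; the
    denominator is the per-position count of covering reads. Positions with
    depth below `min_depth` are reported as missing (NaN).
    """
    n = len(ref.sequence)
    depth = np.zeros(n, dtype=np.int64)
    counts = np.zeros((n, len(SUBSTITUTION_TYPES)), dtype=np.int64)
    type_index = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}
    for rec in records:
        cov = rec.alignment.covered
        depth[cov.start:cov.end] += 1
        if rec.alignment.has_indel:
            continue
        for pos, base in rec.alignment.substitutions:
            counts[pos, type_index[f"{ref.sequence[pos]}>{base}"]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / depth[:, None]
    df = pd.DataFrame(freqs, columns=list(SUBSTITUTION_TYPES))
    for i, base in enumerate(ref.sequence):  # impossible rows (ref base) -> NaN
        for t in SUBSTITUTION_TYPES:
            if not t.startswith(base):
                df.iat[i, type_index[t]] = np.nan
    df[depth < min_depth] = np.nan
    df.insert(0, "depth", depth)
    df.index.name = "position"
    return df


def intended_edit_frequency(records: Sequence[ClassifiedRead]) -> float:
    """Intended-substitution frequency over reads covering the edit locus."""
    denom = sum(1 for r in records if r.covers_edit_locus)
    if denom == 0:
        return 0.0
    return sum(1 for r in records
               if r.covers_edit_locus and r.outcome.has_intended_edit) / denom


def intended_indel_frequency(records: Sequence[ClassifiedRead],
                             ref: AmpliconReference) -> float:
    """Reads whose only indel is exactly the designed one / reads at the nick."""
    if ref.edit is None or ref.edit.kind not in ("insertion", "deletion"):
        raise UsageError("intended_indel_frequency requires an indel edit")
    denom = sum(1 for r in records if r.covers_nick)
    if denom == 0:
        return 0.0
    return sum(1 for r in records
               if r.covers_nick and r.outcome.has_intended_indel_exact) / denom


def unintended_indel_frequency(records: Sequence[ClassifiedRead],
                               mode: str = "substitution_experiment") -> float:
    """Reads with >= 1 unintended indel in the window / reads across the window."""
    if mode not in ("substitution_experiment", "indel_experiment"):
        raise UsageError(f"unknown mode {mode!r}")
    denom = sum(1 for r in records if r.covers_window)
    if denom == 0:
        return 0.0
    num = sum(1 for r in records
              if r.covers_window and r.outcome.has_unintended_indel_in_window)
    return num / denom


def incomplete_and_byproduct_frequencies(
        records: Sequence[ClassifiedRead]) -> tuple[float, float]:
    """(incomplete, byproduct) fractions over reads covering the target site.

    Incomplete products carry only SSMs (no intended edit, no indel, no
    scaffold insertion); byproducts carry only a scaffold-derived insertion.
    """
    denom = sum(1 for r in records if r.covers_edit_locus)
    if denom == 0:
        return 0.0, 0.0
    incomplete = sum(
        1 for r in records
        if r.covers_edit_locus and r.outcome.has_ssm
        and not r.outcome.has_intended_edit
        and not r.alignment.has_indel) / denom
    byproduct = sum(
        1 for r in records
        if r.covers_edit_locus and r.outcome.has_scaffold_incorporation
        and not r.outcome.has_intended_edit and not r.outcome.has_ssm
        and not r.outcome.has_unintended_indel_in_window) / denom
    return incomplete, byproduct


def ot_indel_frequency(reads: Iterable[tuple[str, str]], ot_site: TargetSpec,
                       align_config: AlignConfig | None = None) -> float:
    """Indel frequency at a pegRNA-dependent off-target site.

    Same 80-bp window construction and counting as at the on-target site,
    applied to the off-target locus (which carries its own protospacer/PAM
    geometry); every indel is unintended here.
    """
    ot_ref = AmpliconReference(ot_site, edit=None, ssms=(), scaffold="")
    records = []
    for read in reads:
        aln = align_read(read, ot_ref, align_config)
        rec = classify_read(aln, ot_ref)
        if rec is not None:
            records.append(rec)
    return unintended_indel_frequency(records, "substitution_experiment")


# ---------------------------------------------------------------------------
# End-to-end table


@dataclass
class OutcomeTable:
    """Aggregated outcome frequencies for one amplicon."""

    mode: str
    total_reads: int
    aligned_reads: int
    frequencies: dict[str, float]
    numerators: dict[str, int]
    denominators: dict[str, int]
    substitution_matrix: pd.DataFrame
    depth: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "total_reads": self.total_reads,
            "aligned_reads": self.aligned_reads,
            "frequencies": dict(self.frequencies),
            "numerators": dict(self.numerators),
            "denominators": dict(self.denominators),
        }

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"mode\t{self.mode}")
        lines.append(f"total_reads\t{self.total_reads}")
        lines.append(f"aligned_reads\t{self.aligned_reads}")
        for key, value in self.frequencies.items():
            lines.append(f"{key}\t{value:.6g}")
        return "\n".join(lines) + "\n"


def quantify(reads: Iterable[tuple[str, str]], ref: AmpliconReference,
             mode: str = "auto", min_depth: int = 1000,
             align_config: AlignConfig | None = None,
             detector: ScaffoldDetectorConfig | None = None) -> OutcomeTable:
    """Align, classify and tabulate an amplicon read set."""
    if mode == "auto":
        mode = ("indel" if ref.edit is not None
                and ref.edit.kind in ("insertion", "deletion") else "substitution")
    if mode not in ("substitution", "indel"):
        raise UsageError(f"unknown mode {mode!r}")
    records: list[ClassifiedRead] = []
    total = 0
    for read in reads:
        total += 1
        aln = align_read(read, ref, align_config)
        rec = classify_read(aln, ref, detector)
        if rec is not None:
            records.append(rec)
    freqs: dict[str, float] = {}
    nums: dict[str, int] = {}
    denoms: dict[str, int] = {}
    window_denom = sum(1 for r in records if r.covers_window)
    site_denom = sum(1 for r in records if r.covers_edit_locus)
    if ref.edit is not None and mode == "substitution":
        freqs["intended_edit"] = intended_edit_frequency(records)
        nums["intended_edit"] = sum(1 for r in records if r.covers_edit_locus
                                    and r.outcome.has_intended_edit)
        denoms["intended_edit"] = site_denom
    if mode == "indel" and ref.edit is not None:
        nick_denom = sum(1 for r in records if r.covers_nick)
        freqs["intended_indel"] = intended_indel_frequency(records, ref)
        nums["intended_indel"] = sum(1 for r in records if r.covers_nick
                                     and r.outcome.has_intended_indel_exact)
        denoms["intended_indel"] = nick_denom
    exp_mode = "indel_experiment" if mode == "indel" else "substitution_experiment"
    freqs["unintended_indel"] = unintended_indel_frequency(records, exp_mode)
    nums["unintended_indel"] = sum(1 for r in records if r.covers_window
                                   and r.outcome.has_unintended_indel_in_window)
    denoms["unintended_indel"] = window_denom
    incomplete, byproduct = incomplete_and_byproduct_frequencies(records)
    freqs["incomplete_product"] = incomplete
    freqs["byproduct"] = byproduct
    denoms["incomplete_product"] = denoms["byproduct"] = site_denom
    nums["incomplete_product"] = round(incomplete * site_denom)
    nums["byproduct"] = round(byproduct * site_denom)
    matrix = substitution_frequencies(records, ref, min_depth=min_depth)
    depth = matrix["depth"].to_numpy()
    return OutcomeTable(mode=mode, total_reads=total, aligned_reads=len(records),
                        frequencies=freqs, numerators=nums, denominators=denoms,
                        substitution_matrix=matrix, depth=depth)
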