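"""pegRNA construction and the spegRNA / apegRNA design rules.

A prime-editing guide (pegRNA) is spacer + scaffold + 3' extension, the
extension being the reverse-transcription template (RTT) followed by the
primer-binding site (PBS). The designer implements two engineering rules:

* **spegRNA** — place additional *same-sense* (synonymous) substitutions in
  the RTT. RTT positions are counted with the 3'-terminal base as position 1;
  position p templates the PAM-strand base at nick-relative offset +p, so RTT
  positions and edit offsets share one coordinate system. The productive
  positions are {1}, {5}, {6}, {2,5} and {3,6}; which of them are available
  depends on the register (ORF phase) between the gene's codons and the RTT
  3' end. Phases are labelled by where the wobble (third codon) position
  falls among offsets +1..+3: offset +1 wobble -> ORF2, +2 -> ORF3,
  +3 -> ORF1; the recommended schemes are {3,6} and {6} for ORF1, {1} for
  ORF2, {2,5} and {5} for ORF3.

* **apegRNA** — stabilize the scaffold's small 3'-proximal hairpin either by
  inserting a C/G pair at the bottom of the stem (apegRNA-1) or by replacing
  the (k-1)-th non-C/G pair, counted bottom-up, with a C/G pair (apegRNA-k,
  k >= 2). apegRNA-2 therefore puts a C/G pair at the bottom of the stem.

Both rules can be combined (aspegRNA). Nick placement is fixed 3 nt 5' of
the PAM on the protospacer strand, the standard SpCas9-nickase cut site.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from .errors import (ConflictError, DesignWarning, InfeasibleSchemeError,
                     OutOfFrameError, RangeError, ValidationError,
                     VariantUndefinedError)
from .seqcore import (Interval, ReadingFrameAnnotation, codon_position,
                      complement, matches_pattern, reverse_complement,
                      standard_table, synonymous_alternatives, validate_dna)

# ---------------------------------------------------------------------------
# Targets and edits


@dataclass(frozen=True)
class TargetSpec:
    """A protospacer on a reference sequence, with derived nick coordinate."""

    reference: str
    protospacer: Interval
    strand: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", validate_dna(self.reference, name="reference"))
        object.__setattr__(self, "pam_pattern",
                           validate_dna(self.pam_pattern, allow_n=True, name="pam_pattern"))
        if self.strand not in ("+", "-"):
            raise ValidationError("strand must be '+' or '-'")
        length = len(self.protospacer)
        if not 17 <= length <= 24:
            raise ValidationError(f"protospacer length {length} outside 17-24")
        if self.protospacer.start < 0 or self.protospacer.end > len(self.reference):
            raise RangeError("protospacer outside reference")
        pam = self.pam_interval
        if pam.start < 0 or pam.end > len(self.reference):
            raise RangeError("PAM outside reference")
        if not matches_pattern(self.pam_sequence, self.pam_pattern):
            raise ValidationError(
                f"PAM {self.pam_sequence!r} does not match pattern {self.pam_pattern!r}")

    @property
    def pam_interval(self) -> Interval:
        n = len(self.pam_pattern)
        if self.strand == "+":
            return Interval(self.protospacer.end, self.protospacer.end + n)
        return Interval(self.protospacer.start - n, self.protospacer.start)

    @property
    def pam_sequence(self) -> str:
        seg = self.reference[self.pam_interval.start:self.pam_interval.end]
        return seg if self.strand == "+" else reverse_complement(seg)

    @property
    def nick_coord(self) -> int:
        """Nick boundary, 3 nt 5' of the PAM on the protospacer strand.

        On '+' this is the reference coordinate of the first base 3' of the
        nick (offset +1); on '-' it is the boundary just 5' (plus-orientation
        above) of that base.
        """
        if self.strand == "+":
            return self.protospacer.end - 3
        return self.protospacer.start + 3

    @property
    def spacer(self) -> str:
        seg = self.reference[self.protospacer.start:self.protospacer.end]
        return seg if self.strand == "+" else reverse_complement(seg)

    def offset_to_index(self, offset: int) -> int:
        """Reference index of the PAM-strand base at signed nick-relative offset.

        Offsets are 1-based and signed: +1 is the first base 3' of the nick on
        the protospacer/PAM strand, -1 the first base 5' of it; 0 is invalid.
        """
        if offset == 0:
            raise ValidationError("nick-relative offset 0 is undefined")
        if self.strand == "+":
            idx = self.nick_coord + offset - 1 if offset > 0 else self.nick_coord + offset
        else:
            idx = self.nick_coord - offset if offset > 0 else self.nick_coord - offset - 1
        if not 0 <= idx < len(self.reference):
            raise RangeError(f"offset {offset:+d} outside reference")
        return idx

    def pam_strand_base(self, offset: int) -> str:
        base = self.reference[self.offset_to_index(offset)]
        return base if self.strand == "+" else complement(base)

    def pam_strand_segment(self, start: int, end: int) -> str:
        """PAM-strand sequence 5'->3' spanning signed offsets start..end (inclusive)."""
        if start > end:
            raise ValidationError("segment start > end")
        offsets = [k for k in range(start, end + 1) if k != 0]
        return "".join(self.pam_strand_base(k) for k in offsets)

    @classmethod
    def from_spacer(cls, reference: str, spacer: str, pam_pattern: str = "NGG") -> "TargetSpec":
        """Locate a spacer (protospacer strand sequence) + PAM on the reference."""
        reference = validate_dna(reference, name="reference")
        spacer = validate_dna(spacer, name="spacer")
        n = len(pam_pattern)
        for strand in ("+", "-"):
            query = spacer if strand == "+" else reverse_complement(spacer)
            pos = reference.find(query)
            while pos != -1:
                try:
                    return cls(reference, Interval(pos, pos + len(spacer)), strand,
                               pam_pattern)
                except (ValidationError, RangeError):
                    pos = reference.find(query, pos + 1)
        raise ValidationError("spacer with matching PAM not found in reference")


_SUB_RE = re.compile(r"^\+(\d+)([ACGT]+)-to-([ACGT]+)$")
_INS_RE = re.compile(r"^\+(\d+)([ACGT]+)ins$")
_DEL_RE = re.compile(r"^\+(\d+)([ACGT]+)del$")


@dataclass(frozen=True)
class EditSpec:
    """The intended edit, on the PAM strand, at a 1-based nick-relative offset.

    Names follow the "+5G-to-T" / "+1GATins" / "+2TAdel" convention and
    round-trip through :func:`parse_edit_name`.
    """

    kind: str
    offset: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        if self.offset < 1:
            raise ValidationError("edit offset must be a positive integer")
        object.__setattr__(self, "ref_allele",
                           validate_dna(self.ref_allele, allow_empty=True, name="ref_allele"))
        object.__setattr__(self, "alt_allele",
                           validate_dna(self.alt_allele, allow_empty=True, name="alt_allele"))
        if self.kind == "substitution":
            if not self.ref_allele or len(self.ref_allele) != len(self.alt_allele):
                raise ValidationError("substitution needs equal-length ref/alt alleles")
            if self.ref_allele == self.alt_allele:
                raise ValidationError("substitution alt equals ref")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValidationError("insertion needs empty ref and non-empty alt")
        else:
            if self.alt_allele or not self.ref_allele:
                raise ValidationError("deletion needs non-empty ref and empty alt")

    @property
    def name(self) -> str:
        if self.kind == "substitution":
            return f"+{self.offset}{self.ref_allele}-to-{self.alt_allele}"
        if self.kind == "insertion":
            return f"+{self.offset}{self.alt_allele}ins"
        return f"+{self.offset}{self.ref_allele}del"

    @property
    def length(self) -> int:
        return len(self.alt_allele) if self.kind != "deletion" else len(self.ref_allele)

    def occupied_offsets(self) -> frozenset[int]:
        """Edited-strand offsets written by the edit (empty for deletions)."""
        if self.kind == "deletion":
            return frozenset()
        return frozenset(range(self.offset, self.offset + self.length))

    def validate_against(self, target: TargetSpec) -> None:
        if self.kind in ("substitution", "deletion"):
            seg = target.pam_strand_segment(self.offset, self.offset + len(self.ref_allele) - 1)
            if seg != self.ref_allele:
                raise ValidationError(
                    f"edit ref allele {self.ref_allele!r} does not match reference "
                    f"{seg!r} at offset +{self.offset}")


def parse_edit_name(name: str) -> EditSpec:
    """Parse "+5G-to-T" / "+1GATins" / "+2TAdel" into an EditSpec."""
    name = name.strip()
    if (m := _SUB_RE.match(name)):
        return EditSpec("substitution", int(m.group(1)), m.group(2), m.group(3))
    if (m := _INS_RE.match(name)):
        return EditSpec("insertion", int(m.group(1)), "", m.group(2))
    if (m := _DEL_RE.match(name)):
        return EditSpec("deletion", int(m.group(1)), m.group(2), "")
    raise ValidationError(f"cannot parse edit name {name!r}")


# ---------------------------------------------------------------------------
# Edited-reference bookkeeping (shared by the designer, simulator, quantifier)


class EditedReference:
    """Plus-strand view of the reference with the intended edit applied.

    Maps edited PAM-strand offsets (RTT positions) to plus-strand indices of
    the edited sequence, and original reference coordinates to edited ones.
    """

    def __init__(self, target: TargetSpec, edit: EditSpec | None):
        self.target = target
        self.edit = edit
        ref = target.reference
        if edit is None:
            self.sequence = ref
            self.change_start = len(ref) + 1
            self.old_len = self.new_len = 0
            return
        edit.validate_against(target)
        o, L = edit.offset, edit.length
        if target.strand == "+":
            nick = target.nick_coord
            if edit.kind == "insertion":
                b, old, new = nick + o - 1, "", edit.alt_allele
            else:
                b = nick + o - 1
                old = edit.ref_allele
                new = edit.alt_allele
        else:
            s = target.protospacer.start
            if edit.kind == "insertion":
                b, old, new = s + 4 - o, "", reverse_complement(edit.alt_allele)
            else:
                b = s + 4 - o - len(edit.ref_allele)
                old = reverse_complement(edit.ref_allele)
                new = reverse_complement(edit.alt_allele)
        if b < 0 or b + len(old) > len(ref):
            raise RangeError("edit falls outside the reference")
        if old and ref[b:b + len(old)] != old:
            raise ValidationError("edit ref allele does not match reference")
        self.sequence = ref[:b] + new + ref[b + len(old):]
        self.change_start = b
        self.old_len = len(old)
        self.new_len = len(new)

    @property
    def delta(self) -> int:
        return self.new_len - self.old_len

    def map_coord(self, coord: int) -> int | None:
        """Original reference coordinate -> edited coordinate (None if deleted)."""
        if coord < self.change_start:
            return coord
        if coord < self.change_start + self.old_len:
            return None
        return coord + self.delta

    def map_boundary(self, coord: int) -> int:
        """Map a half-open boundary coordinate, clamping inside a deletion."""
        if coord <= self.change_start:
            return coord
        return max(self.change_start, coord + self.delta)

    def plus_index_of_offset(self, offset: int) -> int:
        """Edited-sequence plus index of edited PAM-strand offset +p (p >= 1)."""
        if offset < 1:
            raise ValidationError("edited offsets are positive")
        t, e = self.target, self.edit
        if t.strand == "+":
            idx = t.nick_coord + offset - 1
        else:
            s = t.protospacer.start
            if e is None or e.kind == "substitution" or offset < e.offset:
                idx = s + 3 - offset
            elif e.kind == "insertion":
                idx = s + 3 + e.length - offset
            else:  # deletion, offset >= e.offset
                idx = s + 3 - offset - e.length
        if not 0 <= idx < len(self.sequence):
            raise RangeError(f"offset +{offset} outside edited reference")
        return idx

    def pam_base(self, offset: int) -> str:
        base = self.sequence[self.plus_index_of_offset(offset)]
        return base if self.target.strand == "+" else complement(base)

    def shifted_frame(self, frame: ReadingFrameAnnotation) -> ReadingFrameAnnotation:
        """Frame annotation in edited coordinates (in-frame edits only)."""
        if self.delta % 3 != 0:
            raise OutOfFrameError("frameshifting edit: synonymy undefined downstream")
        anchor = self.map_coord(frame.frame_anchor)
        if anchor is None:  # anchor deleted; re-anchor on a neighbouring codon
            for k in range(1, len(self.target.reference) // 3 + 1):
                for cand in (frame.frame_anchor - 3 * k, frame.frame_anchor + 3 * k):
                    if frame.cds_interval.contains(cand):
                        mapped = self.map_coord(cand)
                        if mapped is not None:
                            anchor = mapped
                            break
                if anchor is not None:
                    break
            if anchor is None:
                raise OutOfFrameError("cannot re-anchor reading frame after deletion")
        cds = Interval(self.map_boundary(frame.cds_interval.start),
                       self.map_boundary(frame.cds_interval.end))
        return ReadingFrameAnnotation(frame.coding_strand, anchor, cds)


def edited_reference_sequence(target: TargetSpec, edit: EditSpec | None = None,
                              ssms: tuple[tuple[int, str, str], ...] = ()) -> str:
    """Plus-strand reference with intended edit and SSMs applied in silico."""
    eref = EditedReference(target, edit)
    seq = list(eref.sequence)
    for pos, ref_b, alt_b in ssms:
        idx = eref.plus_index_of_offset(pos)
        want = ref_b if target.strand == "+" else complement(ref_b)
        if seq[idx] != want:
            raise ConflictError(f"SSM at +{pos} does not match edited reference")
        seq[idx] = alt_b if target.strand == "+" else complement(alt_b)
    return "".join(seq)


# ---------------------------------------------------------------------------
# pegRNA parts


def build_pbs(target: TargetSpec, pbs_len: int) -> str:
    """Primer-binding site: revcomp of the PAM-strand bases 5' of the nick."""
    if not 1 <= pbs_len <= 17:
        raise RangeError(f"PBS length {pbs_len} outside 1-17")
    try:
        seg = target.pam_strand_segment(-pbs_len, -1)
    except RangeError as exc:
        raise RangeError(f"PBS length {pbs_len} exceeds available sequence") from exc
    return reverse_complement(seg)


def build_rtt(target: TargetSpec, edit: EditSpec | None, rtt_len: int,
              ssms: tuple[tuple[int, str, str], ...] = ()) -> str:
    """Reverse-transcription template covering nick offsets +1..+rtt_len.

    The RTT is the reverse complement of the *edited* PAM-strand segment, so
    its 3'-terminal base (position 1) templates the first nucleotide written
    after the nick. SSMs are (rtt_position, ref_base, alt_base) on the PAM
    strand and must not collide with the edit.
    """
    if rtt_len < 1:
        raise RangeError("RTT length must be positive")
    if edit is not None:
        if edit.kind in ("substitution", "insertion"):
            if edit.offset + edit.length > rtt_len:
                raise RangeError(
                    f"RTT length {rtt_len} does not cover edit {edit.name}")
        elif edit.offset > rtt_len:
            raise RangeError(f"RTT length {rtt_len} does not cover edit {edit.name}")
    eref = EditedReference(target, edit)
    occupied = edit.occupied_offsets() if edit is not None else frozenset()
    bases: list[str] = []
    for p in range(1, rtt_len + 1):
        bases.append(eref.pam_base(p))
    for pos, ref_b, alt_b in ssms:
        if not 1 <= pos <= rtt_len:
            raise RangeError(f"SSM position +{pos} outside RTT of length {rtt_len}")
        if pos in occupied:
            raise ConflictError(f"SSM position +{pos} collides with edit {edit.name}")
        if bases[pos - 1] != ref_b:
            raise ConflictError(
                f"SSM ref base {ref_b} at +{pos} does not match template {bases[pos - 1]}")
        bases[pos - 1] = alt_b
    return reverse_complement("".join(bases))


# ---------------------------------------------------------------------------
# Same-sense mutation placement


@dataclass(frozen=True)
class SSMScheme:
    """A catalog set of RTT positions for same-sense substitutions."""

    positions: frozenset[int]
    orf_label: str = ""

    def __post_init__(self) -> None:
        if not self.positions or len(self.positions) > 2:
            raise ValidationError("catalog schemes carry 1 or 2 positions")
        if not self.positions <= {1, 2, 3, 5, 6}:
            raise ValidationError(f"positions {sorted(self.positions)} outside catalog")

    def __str__(self) -> str:
        return "/".join(str(p) for p in sorted(self.positions))


#: Catalog schemes ranked by the reported median fold improvement
#: (2/5: 1.90, 5: 1.62, 3/6: 1.41, 6: 1.32, 1: 1.28).
RANKED_CATALOG: tuple[frozenset[int], ...] = (
    frozenset({2, 5}), frozenset({5}), frozenset({3, 6}),
    frozenset({6}), frozenset({1}),
)

_RECOMMENDED: dict[str, tuple[frozenset[int], ...]] = {
    "ORF1": (frozenset({3, 6}), frozenset({6})),
    "ORF2": (frozenset({1}),),
    "ORF3": (frozenset({2, 5}), frozenset({5})),
}

_PHASE_BY_WOBBLE_OFFSET = {1: "ORF2", 2: "ORF3", 3: "ORF1"}


def rtt_wobble_phase(target: TargetSpec, frame: ReadingFrameAnnotation) -> str:
    """ORF phase label from which of offsets +1..+3 is a wobble position."""
    wobble = [p for p in (1, 2, 3)
              if codon_position(target.offset_to_index(p), frame) == 3]
    assert len(wobble) == 1, "codon positions cycle with period 3"
    return _PHASE_BY_WOBBLE_OFFSET[wobble[0]]


def recommended_schemes(phase: str) -> list[SSMScheme]:
    """Catalog schemes recommended for a phase, dual scheme first."""
    if phase not in _RECOMMENDED:
        raise ValidationError(f"unknown ORF phase {phase!r}")
    return [SSMScheme(p, phase) for p in _RECOMMENDED[phase]]


def choose_ssm(target: TargetSpec, frame: ReadingFrameAnnotation,
               scheme: SSMScheme, edit: EditSpec | None) -> tuple[tuple[int, str, str], ...]:
    """Pick a synonymous substitution for every scheme position.

    Synonymy is evaluated on the reference carrying the intended edit, so the
    guarantee is relative to the intended product. The tie-break is the
    alphabetically smallest synonymous base (as written on the coding strand);
    substitution type was found immaterial, so determinism wins.
    """
    eref = EditedReference(target, edit)
    eframe = eref.shifted_frame(frame)  # OutOfFrameError for frameshifts
    occupied = edit.occupied_offsets() if edit is not None else frozenset()
    table = standard_table()
    out: list[tuple[int, str, str]] = []
    for pos in sorted(scheme.positions):
        if pos in occupied:
            raise ConflictError(f"scheme position +{pos} collides with the edit")
        idx = eref.plus_index_of_offset(pos)
        if not eframe.cds_interval.contains(idx):
            raise OutOfFrameError(f"scheme position +{pos} outside the CDS")
        cpos = codon_position(idx, eframe)
        if eframe.coding_strand == "+":
            start = idx - (cpos - 1)
            span = Interval(start, start + 3)
            codon = eref.sequence[span.start:span.end]
        else:
            span = Interval(idx + cpos - 3, idx + cpos)
            codon = reverse_complement(eref.sequence[span.start:span.end])
        if span.start < eframe.cds_interval.start or span.end > eframe.cds_interval.end:
            raise OutOfFrameError(f"codon at +{pos} extends beyond the CDS")
        alts = synonymous_alternatives(codon, cpos, table)
        if not alts:
            raise InfeasibleSchemeError(
                f"no synonymous substitution at +{pos} (codon {codon}, position {cpos})")
        alt_coding = min(alts)
        if eframe.coding_strand == target.strand:
            ref_pam, alt_pam = codon[cpos - 1], alt_coding
        else:
            ref_pam, alt_pam = complement(codon[cpos - 1]), complement(alt_coding)
        out.append((pos, ref_pam, alt_pam))
    return tuple(out)


# ---------------------------------------------------------------------------
# Scaffold engineering


#: Canonical 76-nt SpCas9 sgRNA scaffold (DNA alphabet).
SCAFFOLD_76 = ("GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCC"
               "GTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC")

#: 0-based base-pair map of the small 3'-proximal hairpin of SCAFFOLD_76,
#: bottom pair first (stem ACCG/CGGT, loop AGT).
SMALL_HAIRPIN_PAIRS: tuple[tuple[int, int], ...] = ((63, 73), (64, 72), (65, 71), (66, 70))

APEG_VARIANTS = tuple(f"apegRNA-{k}" for k in range(1, 6))


@dataclass(frozen=True)
class ScaffoldModel:
    """Scaffold sequence plus an explicit base-pair map of its hairpins."""

    sequence: str = SCAFFOLD_76
    hairpins: tuple[tuple[tuple[int, int], ...], ...] = (SMALL_HAIRPIN_PAIRS,)
    small_hairpin_index: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, name="scaffold"))
        for hairpin in self.hairpins:
            prev: tuple[int, int] | None = None
            for i, j in hairpin:
                if not (0 <= i < j < len(self.sequence)):
                    raise ValidationError(f"pair ({i},{j}) out of range")
                if prev is not None and not (i > prev[0] and j < prev[1]):
                    raise ValidationError("hairpin pairs must be nested, bottom first")
                prev = (i, j)

    @property
    def small_hairpin(self) -> tuple[tuple[int, int], ...]:
        return self.hairpins[self.small_hairpin_index]


def _is_cg_pair(seq: str, pair: tuple[int, int]) -> bool:
    bases = {seq[pair[0]], seq[pair[1]]}
    return bases == {"C", "G"}


def stabilize_scaffold(model: ScaffoldModel, variant: str) -> str:
    """Return the scaffold sequence of an apegRNA variant.

    apegRNA-1 inserts a C/G pair at the bottom of the small hairpin (+2 nt);
    apegRNA-k (k >= 2) rewrites the (k-1)-th non-C/G pair, bottom-up, to C on
    the 5' side and G on the 3' side.
    """
    if variant not in APEG_VARIANTS:
        raise ValidationError(f"unknown scaffold variant {variant!r}")
    seq = model.sequence
    pairs = model.small_hairpin
    k = int(variant.rsplit("-", 1)[1])
    if k == 1:
        i, j = pairs[0]
        return seq[:i] + "C" + seq[i:j + 1] + "G" + seq[j + 1:]
    non_cg = [p for p in pairs if not _is_cg_pair(seq, p)]
    if len(non_cg) < k - 1:
        raise VariantUndefinedError(
            f"{variant} needs {k - 1} non-C/G pairs, small hairpin has {len(non_cg)}")
    i, j = non_cg[k - 2]
    out = list(seq)
    out[i], out[j] = "C", "G"
    return "".join(out)


def scaffold_sequence(model: ScaffoldModel, variant: str) -> str:
    if variant == "regular":
        return model.sequence
    return stabilize_scaffold(model, variant)


# ---------------------------------------------------------------------------
# Whole-design assembly


@dataclass(frozen=True)
class PegRNADesign:
    """A complete pegRNA: spacer + scaffold + RTT + PBS (DNA alphabet, 5'->3')."""

    name: str
    spacer: str
    scaffold: str
    scaffold_variant: str
    rtt: str
    pbs: str
    ssms: tuple[tuple[int, str, str], ...] = ()
    scheme: frozenset[int] | None = None
    labels: str = ""

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.scaffold + self.rtt + self.pbs

    @property
    def extension(self) -> str:
        return self.rtt + self.pbs


@dataclass(frozen=True)
class DesignParams:
    """Designer knobs. RTT length defaults to max(13, edit 3' end + 6)."""

    pbs_len: int = 13
    rtt_len: int | None = None
    extended: bool = False
    scaffold_model: ScaffoldModel = field(default_factory=ScaffoldModel)
    scaffold_variant: str = "regular"
    max_designs: int = 5


def default_rtt_len(edit: EditSpec | None) -> int:
    if edit is None:
        return 13
    if edit.kind == "deletion":
        end = edit.offset
    else:
        end = edit.offset + edit.length - 1
    return max(13, end + 6)


def _assemble(target: TargetSpec, edit: EditSpec | None,
              ssms: tuple[tuple[int, str, str], ...], scheme: frozenset[int] | None,
              params: DesignParams, label: str) -> PegRNADesign:
    rtt_len = params.rtt_len if params.rtt_len is not None else default_rtt_len(edit)
    if ssms:
        rtt_len = max(rtt_len, max(p for p, _, _ in ssms) + 1)
    rtt = build_rtt(target, edit, rtt_len, ssms)
    pbs = build_pbs(target, params.pbs_len)
    scaffold = scaffold_sequence(params.scaffold_model, params.scaffold_variant)
    edit_tag = edit.name if edit is not None else "noedit"
    ssm_tag = "+".join(str(p) for p, _, _ in ssms) if ssms else "none"
    name = f"{label}_{edit_tag}_ssm{ssm_tag}"
    return PegRNADesign(name=name, spacer=target.spacer, scaffold=scaffold,
                        scaffold_variant=params.scaffold_variant, rtt=rtt, pbs=pbs,
                        ssms=ssms, scheme=scheme, labels=label)


def design_spegrnas(target: TargetSpec, edit: EditSpec | None,
                    frame: ReadingFrameAnnotation,
                    params: DesignParams | None = None) -> list[PegRNADesign]:
    """Emit one spegRNA per feasible SSM scheme, recommended schemes first.

    With `extended`, the remaining catalog schemes are tried afterwards (they
    succeed only where codon position 1 or 2 admits a synonymous change, e.g.
    leucine, arginine or serine codons). At most five designs are emitted and
    every design carries at most four same-sense substitutions.
    """
    params = params or DesignParams()
    phase = rtt_wobble_phase(target, frame)
    scheme_sets: list[frozenset[int]] = list(_RECOMMENDED[phase])
    if params.extended:
        scheme_sets += [s for s in RANKED_CATALOG if s not in scheme_sets]
    designs: list[PegRNADesign] = []
    for positions in scheme_sets:
        if len(designs) >= min(params.max_designs, 5):
            break
        scheme = SSMScheme(positions, phase)
        try:
            ssms = choose_ssm(target, frame, scheme, edit)
        except (InfeasibleSchemeError, ConflictError, OutOfFrameError):
            continue
        if len(ssms) > 4:  # unreachable with catalog schemes; hard guarantee
            continue
        designs.append(_assemble(target, edit, ssms, positions, params, "speg"))
    if not designs:
        warnings.warn("no feasible SSM scheme at this target; use the regular pegRNA",
                      DesignWarning, stacklevel=2)
    return designs


def design_aspegrna(target: TargetSpec, edit: EditSpec | None,
                    frame: ReadingFrameAnnotation | None,
                    params: DesignParams | None = None) -> list[PegRNADesign]:
    """spegRNA schemes combined with the apegRNA-2 stabilized scaffold.

    For indel edits without a usable reading frame (no annotation, or a
    frameshifting length) the stabilized scaffold is still emitted, with an
    empty SSM set and a warning.
    """
    params = replace(params or DesignParams(), scaffold_variant="apegRNA-2")
    frameshift = edit is not None and edit.kind != "substitution" and edit.length % 3 != 0
    if frame is None or frameshift:
        warnings.warn("no usable reading frame: emitting apegRNA-2 without SSMs",
                      DesignWarning, stacklevel=2)
        return [_assemble(target, edit, (), None, params, "apeg")]
    designs = design_spegrnas(target, edit, frame, params)
    if not designs:
        return [_assemble(target, edit, (), None, params, "apeg")]
    return [replace(d, name=d.name.replace("speg", "aspeg", 1), labels="aspeg")
            for d in designs]


# ---------------------------------------------------------------------------
# Nicking sgRNA and cloning oligos


@dataclass(frozen=True)
class NickSgRNACandidate:
    spacer: str
    protospacer: Interval
    strand: str
    nick_coord: int
    distance: int


def design_nick_sgrna(target: TargetSpec, window: tuple[int, int] = (40, 100),
                      spacer_len: int = 20) -> list[NickSgRNACandidate]:
    """All opposite-strand spacers with a valid PAM nicking within the window.

    Distance is measured between the candidate nick and the pegRNA nick;
    candidates are sorted by distance (then coordinate).
    """
    lo, hi = window
    if lo > hi or lo < 0:
        raise ValidationError("window must be (lo, hi) with 0 <= lo <= hi")
    ref = target.reference
    other = "-" if target.strand == "+" else "+"
    out: list[NickSgRNACandidate] = []
    for start in range(0, len(ref) - spacer_len + 1):
        interval = Interval(start, start + spacer_len)
        try:
            cand = TargetSpec(ref, interval, other, target.pam_pattern)
        except (ValidationError, RangeError):
            continue
        dist = abs(cand.nick_coord - target.nick_coord)
        if lo <= dist <= hi:
            out.append(NickSgRNACandidate(cand.spacer, interval, other,
                                          cand.nick_coord, dist))
    out.sort(key=lambda c: (c.distance, c.protospacer.start))
    return out


@dataclass(frozen=True)
class OligoPair:
    forward: str
    reverse: str


@dataclass(frozen=True)
class OverhangConfig:
    """5' overhangs added to annealed cloning oligos (plasmid-specific)."""

    spacer_forward: str = "ACCG"
    spacer_reverse: str = "AAAC"
    extension_forward: str = ""
    extension_reverse: str = ""


def emit_oligos(design: PegRNADesign,
                overhangs: OverhangConfig | None = None) -> tuple[OligoPair, OligoPair]:
    """Spacer oligo pair and 3'-extension (RTT+PBS) oligo pair."""
    cfg = overhangs or OverhangConfig()
    spacer_pair = OligoPair(cfg.spacer_forward + design.spacer,
                            cfg.spacer_reverse + reverse_complement(design.spacer))
    ext = design.extension
    ext_pair = OligoPair(cfg.extension_forward + ext,
                         cfg.extension_reverse + reverse_complement(ext))
    return spacer_pair, ext_pair


# ---------------------------------------------------------------------------
# Translation helper (used by the same-sense guarantee and its tests)


def translate_frame(sequence: str, frame: ReadingFrameAnnotation) -> str:
    """Translate the full codons of the CDS, aligned to the frame anchor."""
    table = standard_table()
    cds = frame.cds_interval
    aas: list[str] = []
    if frame.coding_strand == "+":
        start = frame.frame_anchor
        while start - 3 >= cds.start:
            start -= 3
        for c in range(start, cds.end - 2, 3):
            aas.append(table.amino_acid(sequence[c:c + 3]))
    else:
        start = frame.frame_anchor  # 5' base (highest plus coordinate) of a codon
        while start + 3 <= cds.end - 1:
            start += 3
        c = start
        while c - 2 >= cds.start:
            aas.append(table.amino_acid(reverse_complement(sequence[c - 2:c + 1])))
            c -= 3
    return "".join(aas)
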