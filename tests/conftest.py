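"""Shared fixtures: toy targets with known codon structure and random
amplicon builders used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import spegkit as sk
from spegkit.seqcore import Interval, ReadingFrameAnnotation


@pytest.fixture
def toy_target() -> sk.TargetSpec:
    """20-nt protospacer, nick after position 17, downstream segment GGTGCTAAA.

    The downstream codons (coding strand = PAM strand, anchor at the nick)
    are GGT|GCT|AAA: glycine, alanine, lysine. PAM pattern is relaxed to NNN
    because the toy segment intentionally overlaps the PAM positions.
    """
    proto = "ACGTACGTACGTACGTA" + "GGT"
    ref = proto + "GCTAAA" + "ACCGTTGGATCCAGG"
    return sk.TargetSpec(ref, Interval(0, 20), "+", pam_pattern="NNN")


@pytest.fixture
def toy_frame() -> ReadingFrameAnnotation:
    return ReadingFrameAnnotation("+", 17, Interval(17, 32))


@pytest.fixture
def toy_edit() -> sk.EditSpec:
    """Substitution at +7, outside the codons probed by the catalog schemes."""
    return sk.EditSpec("substitution", 7, "A", "C")


def make_plus_target(rng: np.random.Generator, length: int = 250,
                     proto_start: int = 100) -> sk.TargetSpec:
    """Random amplicon with a 20-nt plus-strand protospacer and NGG PAM."""
    seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, length)))
    seq[proto_start + 21] = "G"
    seq[proto_start + 22] = "G"
    return sk.TargetSpec("".join(seq), Interval(proto_start, proto_start + 20), "+")


def make_minus_target(rng: np.random.Generator, length: int = 250,
                      proto_start: int = 100) -> sk.TargetSpec:
    seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, length)))
    seq[proto_start - 3] = "C"
    seq[proto_start - 2] = "C"
    return sk.TargetSpec("".join(seq), Interval(proto_start, proto_start + 20), "-")


def random_coding_target(rng: np.random.Generator, coding_strand: str
                         ) -> tuple[sk.TargetSpec, ReadingFrameAnnotation, sk.EditSpec]:
    """Random target + frame + substitution edit with the CDS spanning the nick."""
    target = make_plus_target(rng) if rng.random() < 0.5 else make_minus_target(rng)
    cds = Interval(60, 180)
    phase = int(rng.integers(0, 3))
    anchor = cds.start + phase if coding_strand == "+" else cds.end - 1 - phase
    frame = ReadingFrameAnnotation(coding_strand, anchor, cds)
    offset = int(rng.integers(1, 10))
    ref_base = target.pam_strand_base(offset)
    alt = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
    return target, frame, sk.EditSpec("substitution", offset, ref_base, alt)


def substitution_amplicon(seed: int = 7) -> tuple[sk.AmpliconReference, sk.EditSpec]:
    """Amplicon + designed spegRNA for a +5 substitution (used end-to-end)."""
    rng = np.random.default_rng(seed)
    target = make_plus_target(rng)
    frame = ReadingFrameAnnotation("+", 117, Interval(90, 180))
    ref_base = target.pam_strand_base(5)
    alt = "T" if ref_base != "T" else "A"
    edit = sk.EditSpec("substitution", 5, ref_base, alt)
    designs = sk.design_spegrnas(target, edit, frame)
    assert designs, "fixture target must admit at least one scheme"
    return sk.AmpliconReference.from_design(target, edit, designs[0]), edit


def indel_amplicon(seed: int = 11) -> sk.AmpliconReference:
    rng = np.random.default_rng(seed)
    target = make_plus_target(rng, length=260)
    edit = sk.parse_edit_name("+1GATins")
    return sk.AmpliconReference(target, edit, ssms=(), scaffold=sk.SCAFFOLD_76)
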