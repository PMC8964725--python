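"""Seeded amplicon-read simulator with known outcome-class proportions.

Six read classes are emulated by applying the corresponding events to the
amplicon reference: `unedited`, `intended_only`, `intended_plus_ssm`,
`ssm_only` (the incomplete product), `unintended_indel` (a random 1-3 nt
indel inside the quantification window, kept > 5 nt away from the nick so
it can never mimic scaffold incorporation), and `scaffold_byproduct` (a
4-8 nt insertion at the nick templated from the scaffold 3' end). Class
counts follow largest-remainder rounding of the requested proportions;
uniform substitution errors are applied on top. A fixed seed makes the
FASTQ byte-identical across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import RangeError, UsageError, ValidationError
from .outcome_quant import AmpliconReference, quant_window
from .pegdesign import edited_reference_sequence
from .seqcore import complement, reverse_complement

CLASSES = ("unedited", "intended_only", "intended_plus_ssm", "ssm_only",
           "unintended_indel", "scaffold_byproduct")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters: class proportions, read count, error model, seed."""

    proportions: Mapping[str, float]
    n_reads: int = 1000
    read_length: int = 0  # 0 = full amplicon
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(CLASSES)
        if unknown:
            raise ValidationError(f"unknown read classes: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError("proportions must be non-negative")
        if self.n_reads <= 0:
            raise ValidationError("n_reads must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValidationError("error_rate must be in [0, 0.25)")


def class_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of proportions to integer class counts."""
    ordered = [(cls, proportions.get(cls, 0.0)) for cls in CLASSES]
    raw = [(cls, p * n) for cls, p in ordered]
    counts = {cls: int(np.floor(x)) for cls, x in raw}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda cp: (-(cp[1] - np.floor(cp[1])), CLASSES.index(cp[0])))
    for cls, _ in by_frac[:remainder]:
        counts[cls] += 1
    return counts


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    truth_class: str


def _class_template(ref: AmpliconReference, cls: str,
                    rng: np.random.Generator) -> str:
    """Amplicon template carrying the class's events (plus strand)."""
    target, edit = ref.target, ref.edit
    if cls == "unedited":
        return ref.sequence
    if cls == "intended_only":
        if edit is None:
            raise UsageError("intended classes need an intended edit")
        return edited_reference_sequence(target, edit)
    if cls == "intended_plus_ssm":
        if edit is None:
            raise UsageError("intended classes need an intended edit")
        return edited_reference_sequence(target, edit, ref.ssms)
    if cls == "ssm_only":
        if not ref.ssms:
            raise UsageError("ssm classes need designed SSMs")
        seq = list(ref.sequence)
        for idx, ref_plus, alt_plus in ref.ssm_plus_positions():
            if seq[idx] != ref_plus:
                raise ValidationError("SSM does not match the reference")
            seq[idx] = alt_plus
        return "".join(seq)
    if cls == "unintended_indel":
        window = quant_window(ref)
        nick = ref.nick_plus
        size = int(rng.integers(1, 4))
        kind = "del" if rng.random() < 0.5 else "ins"
        # keep > 5 nt from the nick: a random insertion there could satisfy
        # the scaffold-incorporation detector and break class exactness
        lo, hi = window.start, window.end - size
        for _ in range(100):
            pos = int(rng.integers(lo, hi))
            if abs(pos - nick) > 5 + size:
                break
        else:
            raise RangeError("no indel position available outside the nick zone")
        seq = ref.sequence
        if kind == "del":
            return seq[:pos] + seq[pos + size:]
        ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size))
        return seq[:pos] + ins + seq[pos:]
    if cls == "scaffold_byproduct":
        if not ref.scaffold:
            raise UsageError("scaffold_byproduct needs a scaffold sequence")
        length = int(rng.integers(4, 9))
        ins_pam = reverse_complement(ref.scaffold)[:length]
        ins_plus = ins_pam if target.strand == "+" else reverse_complement(ins_pam)
        nick = ref.nick_plus
        seq = ref.sequence
        return seq[:nick] + ins_plus + seq[nick:]
    raise ValidationError(f"unknown class {cls!r}")


def _window_slice(template: str, ref: AmpliconReference, read_length: int) -> str:
    if read_length <= 0 or read_length >= len(template):
        return template
    window = quant_window(ref)
    center = (window.start + window.end) // 2
    start = min(max(0, center - read_length // 2), len(template) - read_length)
    return template[start:start + read_length]


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    if len(hit):
        # replace with a uniform choice among the three alternative bases
        shifts = rng.integers(1, 4, len(hit))
        codes = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(codes + shifts) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(ref: AmpliconReference, spec: SimSpec
                   ) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Generate reads plus a truth table of per-read classes.

    Returns (reads, truth) where truth has columns read_id / truth_class.
    The read order (and hence the FASTQ byte stream) is fully determined by
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    counts = class_counts(spec.proportions, spec.n_reads)
    reads: list[SimulatedRead] = []
    k = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            template = _class_template(ref, cls, rng)
            seq = _window_slice(template, ref, spec.read_length)
            seq = _apply_errors(seq, spec.error_rate, rng)
            reads.append(SimulatedRead(f"read_{k:06d}", seq, cls))
            k += 1
    truth = pd.DataFrame({"read_id": [r.read_id for r in reads],
                          "truth_class": [r.truth_class for r in reads]})
    return reads, truth


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Standard 4-line FASTQ with constant Q40 ('I') qualities."""
    with open(path, "w") as handle:
        handle.write(fastq_text(reads))


def fastq_text(reads: list[SimulatedRead]) -> str:
    buf = io.StringIO()
    for read in reads:
        buf.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
    return buf.getvalue()
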