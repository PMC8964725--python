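"""Exhaustive mismatch-tolerant off-target scan (Cas-OFFinder-style settings).

Every position on both strands of every subject sequence is tested: the PAM
pattern (default NGG, N = any of A/C/G/T) gates the site and the Hamming
distance between the spacer and the site 20-mer is counted; PAM mismatches
are a gate, not counted. N in the subject never matches anything. No
DNA/RNA-bulge search is performed — prediction here is mismatch-only, with a
default ceiling of 5 mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .seqcore import Interval, reverse_complement, validate_dna

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate site; `interval` is in plus-strand subject coordinates."""

    seq_id: str
    interval: Interval
    strand: str
    site_sequence: str
    pam_observed: str
    mismatch_count: int


def _scan_one_strand(spacer_code: np.ndarray, subject: str, pam: str,
                     max_mismatches: int) -> list[tuple[int, int, str]]:
    """(start, mismatches, pam_observed) on the forward orientation of `subject`."""
    L, P = len(spacer_code), len(pam)
    n = len(subject)
    if n < L + P:
        return []
    code = _encode(subject)
    windows = np.lib.stride_tricks.sliding_window_view(code, L)[: n - L - P + 1]
    mism = (windows != spacer_code).sum(axis=1)
    # subject N (encoded 255) never matches, already counted as mismatch above
    pam_ok = np.ones(len(windows), dtype=bool)
    for k, pat in enumerate(pam.upper()):
        col = code[L + k: L + k + len(windows)]
        if pat == "N":
            pam_ok &= col < 4
        else:
            pam_ok &= col == _ENCODE[ord(pat)]
    keep = np.flatnonzero(pam_ok & (mism <= max_mismatches))
    return [(int(i), int(mism[i]), subject[i + L: i + L + P].upper()) for i in keep]


def scan_offtargets(spacer: str,
                    subjects: Sequence[tuple[str, str]] | dict[str, str] | str,
                    max_mismatches: int = 5,
                    pam_pattern: str = "NGG") -> list[OffTargetHit]:
    """Scan subject sequences for spacer-like sites followed by a PAM.

    `subjects` may be a bare sequence, a {name: sequence} mapping, or a list
    of (name, sequence) pairs. Hits are sorted by (sequence name, coordinate).
    """
    spacer = validate_dna(spacer, name="spacer")
    if not 17 <= len(spacer) <= 24:
        raise ValidationError(f"spacer length {len(spacer)} outside 17-24")
    pam_pattern = validate_dna(pam_pattern, allow_n=True, name="pam_pattern")
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    if isinstance(subjects, str):
        items: Iterable[tuple[str, str]] = [("subject", subjects)]
    elif isinstance(subjects, dict):
        items = subjects.items()
    else:
        items = subjects
    spacer_code = _encode(spacer)
    L, P = len(spacer), len(pam_pattern)
    hits: list[OffTargetHit] = []
    for seq_id, subject in items:
        subject = subject.upper()
        n = len(subject)
        for start, mm, pam_obs in _scan_one_strand(spacer_code, subject,
                                                   pam_pattern, max_mismatches):
            hits.append(OffTargetHit(seq_id, Interval(start, start + L), "+",
                                     subject[start:start + L], pam_obs, mm))
        rc = reverse_complement(subject)
        for start, mm, pam_obs in _scan_one_strand(spacer_code, rc,
                                                   pam_pattern, max_mismatches):
            plus_start = n - start - L
            hits.append(OffTargetHit(seq_id, Interval(plus_start, plus_start + L), "-",
                                     rc[start:start + L], pam_obs, mm))
    hits.sort(key=lambda h: (h.seq_id, h.interval.start, h.strand))
    return hits


def hits_to_bed(hits: Iterable[OffTargetHit]) -> str:
    """6-column BED text (chrom, start, end, name=site, score=mismatches, strand)."""
    lines = [
        f"{h.seq_id}\t{h.interval.start}\t{h.interval.end}\t{h.site_sequence}"
        f"\t{h.mismatch_count}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
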