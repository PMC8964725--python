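"""Read alignment, outcome classification and the frequency formulas."""

import numpy as np
import pytest

import spegkit as sk
from spegkit.errors import RangeError, UsageError
from spegkit.outcome_quant import (AlignConfig, ReadAlignment, align_read,
                                   classify_read, detect_scaffold_incorporation,
                                   quant_window, substitution_frequencies)
from spegkit.seqcore import Interval

from conftest import indel_amplicon, make_minus_target, make_plus_target, \
    substitution_amplicon


def _oracle_score(q, r, match=2, mism=-4, go=6, ge=1):
    """Independent quadratic-time affine-gap DP (score only)."""
    NEG = -10 ** 9
    m, n = len(q), len(r)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0
    for i in range(1, m + 1):
        X[i][0] = -(go + i * ge)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if q[i - 1] == r[j - 1] else mism
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge)
    return max(max(M[m][j], X[m][j]) for j in range(n + 1))


class TestQuantWindow:
    def test_plus_strand_80bp(self):
        rng = np.random.default_rng(0)
        target = make_plus_target(rng, length=300, proto_start=100)
        ref = sk.AmpliconReference(target)
        window = quant_window(ref)
        assert (window.start, window.end) == (92, 172)
        assert len(window) == 80

    def test_minus_strand_mirrored(self):
        rng = np.random.default_rng(1)
        target = make_minus_target(rng, length=300, proto_start=100)
        window = quant_window(sk.AmpliconReference(target))
        assert (window.start, window.end) == (48, 128)
        assert len(window) == 80

    def test_near_edge_raises(self):
        rng = np.random.default_rng(2)
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 60)))
        seq[25] = "G"
        seq[26] = "G"
        target = sk.TargetSpec("".join(seq), Interval(4, 24), "+")
        with pytest.raises(RangeError):
            quant_window(sk.AmpliconReference(target))

    @pytest.mark.parametrize("proto_len", [17, 20, 24])
    def test_length_is_60_plus_protospacer(self, proto_len):
        rng = np.random.default_rng(proto_len)
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 300)))
        seq[100 + proto_len + 1] = "G"
        seq[100 + proto_len + 2] = "G"
        target = sk.TargetSpec("".join(seq), Interval(100, 100 + proto_len), "+")
        assert len(quant_window(sk.AmpliconReference(target))) == 60 + proto_len


class TestAligner:
    def test_identity_read(self):
        amp, _ = substitution_amplicon()
        aln = align_read(("r", amp.sequence[40:200]), amp)
        assert aln.aligned and not aln.substitutions and not aln.has_indel
        assert (aln.covered.start, aln.covered.end) == (40, 200)

    def test_single_substitution_located(self):
        amp, _ = substitution_amplicon()
        seq = list(amp.sequence[30:210])
        seq[70] = "A" if seq[70] != "A" else "C"
        aln = align_read(("r", "".join(seq)), amp)
        assert aln.substitutions == frozenset({(100, "".join(seq)[70])})

    def test_random_read_not_aligned(self):
        amp, _ = substitution_amplicon()
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[b] for b in rng.integers(0, 4, 150))
        assert not align_read(("r", junk), amp).aligned

    def test_short_read_excluded(self):
        amp, _ = substitution_amplicon()
        assert not align_read(("r", amp.sequence[:20]), amp).aligned

    def test_score_matches_dp_oracle_on_small_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(120):
            n = int(rng.integers(30, 61))
            m = int(rng.integers(30, n + 1))
            r = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
            q = "".join("ACGT"[b] for b in rng.integers(0, 4, m))
            from spegkit._gotoh import semiglobal_align
            score, _, _ = semiglobal_align(q, r)
            assert score == _oracle_score(q, r)

    def test_banded_equals_full_on_simulated_classes(self):
        amp, _ = substitution_amplicon()
        spec = sk.SimSpec({"unedited": 0.25, "intended_only": 0.25,
                           "unintended_indel": 0.25, "scaffold_byproduct": 0.25},
                          n_reads=80, seed=12)
        reads, _ = sk.simulate_reads(amp, spec)
        full = AlignConfig(band=None)
        banded = AlignConfig(band=24)
        for read in reads:
            a = align_read((read.read_id, read.sequence), amp, full)
            b = align_read((read.read_id, read.sequence), amp, banded)
            assert a.score == b.score
            assert a.substitutions == b.substitutions
            assert a.insertions == b.insertions and a.deletions == b.deletions


class TestClassification:
    def test_perfect_intended_read(self):
        amp, _ = substitution_amplicon()
        edited = sk.edited_reference_sequence(amp.target, amp.edit)
        rec = classify_read(align_read(("r", edited), amp), amp)
        out = rec.outcome
        assert out.has_intended_edit and not out.has_ssm
        assert not out.has_unintended_indel_in_window
        assert not out.has_scaffold_incorporation

    def test_ssm_only_read_is_incomplete_product(self):
        amp, _ = substitution_amplicon()
        edited = sk.edited_reference_sequence(amp.target, None, amp.ssms)
        rec = classify_read(align_read(("r", edited), amp), amp)
        assert rec.outcome.has_ssm and not rec.outcome.has_intended_edit

    def test_deletion_window_boundary(self):
        """1-nt deletion 30 nt 3' of the PAM is in-window; 60 nt is not."""
        amp, _ = substitution_amplicon()
        pam_end = amp.target.pam_interval.end
        for dist, expected in ((30, True), (60, False)):
            pos = pam_end + dist
            seq = amp.sequence[:pos] + amp.sequence[pos + 1:]
            rec = classify_read(align_read(("r", seq), amp), amp)
            assert rec.outcome.has_unintended_indel_in_window is expected

    def test_uncovering_read_excluded_from_edit_denominator(self):
        amp, _ = substitution_amplicon()
        rec = classify_read(align_read(("r", amp.sequence[:100]), amp), amp)
        assert rec is not None and not rec.covers_edit_locus


class TestQualityTrim:
    def test_trims_low_quality_ends_only(self):
        seq = "ACGTACGTAC"
        quals = [10, 20, 35, 40, 40, 40, 35, 31, 12, 5]
        assert sk.trim_read_ends(seq, quals, 30) == "GTACGT"
        assert sk.trim_read_ends(seq, quals, 5) == seq
        assert sk.trim_read_ends(seq, [1] * 10, 30) == ""


class TestScaffoldDetector:
    def test_scaffold_tail_insertion_detected(self):
        amp, _ = substitution_amplicon()
        nick = amp.nick_plus
        assert sk.SCAFFOLD_76.endswith("GTCGGTGC")
        aln = ReadAlignment("r", True, insertions=((nick, "GCACC"),),
                            covered=Interval(0, len(amp.sequence)))
        assert detect_scaffold_incorporation(aln, amp)

    def test_unrelated_insertion_rejected(self):
        amp, _ = substitution_amplicon()
        aln = ReadAlignment("r", True, insertions=((amp.nick_plus, "TTTTT"),),
                            covered=Interval(0, len(amp.sequence)))
        assert not detect_scaffold_incorporation(aln, amp)

    def test_below_length_floor_rejected(self):
        amp, _ = substitution_amplicon()
        aln = ReadAlignment("r", True, insertions=((amp.nick_plus, "GC"),),
                            covered=Interval(0, len(amp.sequence)))
        assert not detect_scaffold_incorporation(aln, amp)

    def test_far_from_nick_rejected(self):
        amp, _ = substitution_amplicon()
        aln = ReadAlignment("r", True, insertions=((amp.nick_plus + 30, "GCACC"),),
                            covered=Interval(0, len(amp.sequence)))
        assert not detect_scaffold_incorporation(aln, amp)


def _quantify_reads(amp, reads, min_depth=1):
    return sk.quantify(reads, amp, min_depth=min_depth)


class TestFrequencies:
    def test_substitution_frequency_hand_count(self):
        """4 intended-edit reads without indel, 1 indel read, 5 unedited -> 0.40."""
        amp, edit = substitution_amplicon()
        edited = sk.edited_reference_sequence(amp.target, edit)
        indel_read = amp.sequence[:50] + amp.sequence[52:]
        reads = ([("e%d" % i, edited) for i in range(4)]
                 + [("d", indel_read)]
                 + [("u%d" % i, amp.sequence) for i in range(5)])
        table = _quantify_reads(amp, reads, min_depth=10)
        edit_pos = amp.target.offset_to_index(edit.offset)
        col = f"{amp.sequence[edit_pos]}>{edit.alt_allele}"
        assert table.substitution_matrix.loc[edit_pos, col] == pytest.approx(0.40)
        assert table.frequencies["intended_edit"] == pytest.approx(0.40)

    def test_depth_threshold_boundary(self):
        """Frequencies reported at depth >= min_depth and missing below."""
        amp, edit = substitution_amplicon()
        edited = sk.edited_reference_sequence(amp.target, edit)
        reads = [("r%d" % i, edited) for i in range(40)]
        records = []
        from spegkit.outcome_quant import classify_read as cr
        for read in reads:
            records.append(cr(align_read(read, amp), amp))
        edit_pos = amp.target.offset_to_index(edit.offset)
        col = f"{amp.sequence[edit_pos]}>{edit.alt_allele}"
        present = substitution_frequencies(records, amp, min_depth=40)
        missing = substitution_frequencies(records, amp, min_depth=41)
        assert present.loc[edit_pos, col] == pytest.approx(1.0)
        assert np.isnan(missing.loc[edit_pos, col])

    def test_intended_indel_only_counts_pure_reads(self):
        """6 exact insertions, 1 insertion+extra deletion, 3 unedited -> 0.60."""
        amp = indel_amplicon()
        edited = sk.edited_reference_sequence(amp.target, amp.edit)
        win = quant_window(amp)  # extra deletion placed inside the window
        cut = win.end - 5
        compound = edited[:cut] + edited[cut + 1:]
        reads = ([("i%d" % i, edited) for i in range(6)]
                 + [("c", compound)]
                 + [("u%d" % i, amp.sequence) for i in range(3)])
        table = _quantify_reads(amp, reads)
        assert table.frequencies["intended_indel"] == pytest.approx(0.60)
        assert table.frequencies["unintended_indel"] == pytest.approx(0.10)

    def test_intended_indel_frequency_rejects_substitution_edit(self):
        amp, _ = substitution_amplicon()
        with pytest.raises(UsageError):
            sk.intended_indel_frequency([], amp)

    def test_unintended_indel_substitution_experiment(self):
        """2 indel reads of 20 aligned -> 0.10."""
        amp, _ = substitution_amplicon()
        pos = amp.target.pam_interval.end + 20
        indel_read = amp.sequence[:pos] + amp.sequence[pos + 2:]
        reads = ([("d%d" % i, indel_read) for i in range(2)]
                 + [("u%d" % i, amp.sequence) for i in range(18)])
        table = _quantify_reads(amp, reads)
        assert table.frequencies["unintended_indel"] == pytest.approx(0.10)

    def test_incomplete_and_byproduct_fractions(self):
        amp, _ = substitution_amplicon()
        ssm_only = sk.edited_reference_sequence(amp.target, None, amp.ssms)
        tail = sk.reverse_complement(amp.scaffold)[:6]
        nick = amp.nick_plus
        byprod = amp.sequence[:nick] + tail + amp.sequence[nick:]
        reads = ([("s", ssm_only)] + [("b%d" % i, byprod) for i in range(2)]
                 + [("u%d" % i, amp.sequence) for i in range(7)])
        table = _quantify_reads(amp, reads)
        assert table.frequencies["incomplete_product"] == pytest.approx(0.10)
        assert table.frequencies["byproduct"] == pytest.approx(0.20)

    def test_read_with_edit_and_ssm_counts_in_neither(self):
        amp, _ = substitution_amplicon()
        both = sk.edited_reference_sequence(amp.target, amp.edit, amp.ssms)
        table = _quantify_reads(amp, [("r", both)] * 5)
        assert table.frequencies["incomplete_product"] == 0.0
        assert table.frequencies["byproduct"] == 0.0
        assert table.frequencies["intended_edit"] == 1.0

    def test_partition_sanity_and_denominators(self):
        amp, _ = substitution_amplicon()
        spec = sk.SimSpec({"unedited": 0.3, "intended_only": 0.2,
                           "intended_plus_ssm": 0.1, "ssm_only": 0.2,
                           "unintended_indel": 0.1, "scaffold_byproduct": 0.1},
                          n_reads=300, seed=21)
        reads, _ = sk.simulate_reads(amp, spec)
        table = _quantify_reads(amp, [(r.read_id, r.sequence) for r in reads])
        for key, num in table.numerators.items():
            assert 0 <= num <= table.denominators[key]
        for value in table.frequencies.values():
            assert 0.0 <= value <= 1.0
        # per read, at most one of {incomplete, byproduct}
        from spegkit.outcome_quant import classify_read as cr
        for r in reads:
            rec = cr(align_read((r.read_id, r.sequence), amp), amp)
            out = rec.outcome
            incomplete = (out.has_ssm and not out.has_intended_edit
                          and not rec.alignment.has_indel)
            byproduct = (out.has_scaffold_incorporation and not out.has_ssm
                         and not out.has_intended_edit
                         and not out.has_unintended_indel_in_window)
            assert not (incomplete and byproduct)


class TestOffTargetIndels:
    def test_planted_ot_indel_fraction_exact(self):
        rng = np.random.default_rng(31)
        ot_target = make_plus_target(rng, length=260, proto_start=110)
        seq = ot_target.reference
        pos = ot_target.pam_interval.end + 10
        indel_read = seq[:pos] + seq[pos + 2:]
        reads = [("d%d" % i, indel_read) for i in range(200)] + \
                [("u%d" % i, seq) for i in range(1800)]
        freq = sk.ot_indel_frequency(reads, ot_target)
        assert freq == pytest.approx(0.10)

    def test_no_indel_reads(self):
        rng = np.random.default_rng(32)
        ot_target = make_plus_target(rng, length=260, proto_start=110)
        freq = sk.ot_indel_frequency([("u", ot_target.reference)] * 50, ot_target)
        assert freq == 0.0
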