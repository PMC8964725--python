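# spegkit

Prime editors (PE) copy an edit from the 3' extension of a prime-editing
guide RNA (pegRNA) into genomic DNA, but their efficiency is often limited
by mismatch repair (MMR): a single programmed base-base mismatch in the
repair heteroduplex is resolved inefficiently. Two guide-engineering
strategies counter this:

* **spegRNA** — add *same-sense mutations* (SSMs, synonymous substitutions)
  at productive positions of the reverse-transcription template (RTT).
  Counting the RTT 3'-terminal base as position 1, the productive positions
  are **{1}, {5}, {6}, {2,5} and {3,6}**; which of them admit a synonymous
  change depends on the register ("ORF phase") between the gene's codons and
  the RTT 3' end. With the wobble position at nick offset +3 (**ORF1**) the
  schemes {3,6} and {6} apply; at +1 (**ORF2**), scheme {1}; at +2
  (**ORF3**), schemes {2,5} and {5}. Any emitted design carries at most four
  additional substitutions, and no target needs more than five spegRNAs.
* **apegRNA** — stabilize the small 3'-proximal scaffold hairpin, which the
  freely swinging RTT/PBS extension can melt, by inserting a C/G pair at the
  bottom of the stem (apegRNA-1) or rewriting the (k−1)-th non-C/G pair,
  bottom-up, to C/G (apegRNA-k). apegRNA-2 — a C/G pair at the very bottom —
  is the preferred variant; both rules combine into **aspegRNA**.

`spegkit` implements the complete design rules, a Cas-OFFinder-style
mismatch-only off-target scan (≤ 5 mismatches by default), a seeded
amplicon-read simulator, and an outcome quantifier that reproduces the
standard amplicon-sequencing frequency definitions:

* per-position base-substitution frequency = reads with the substitution
  and no indel / covering reads, reported only at depth ≥ 1000;
* unintended-indel frequency inside the window from 8 nt upstream of the
  protospacer to 52 nt downstream of its 3' end (80 bp for a 20-nt
  protospacer);
* intended-indel frequency (reads whose *only* indel is the designed one);
* incomplete products (SSMs without the intended edit) and byproducts
  (pegRNA scaffold incorporation at the nick).

A statistics layer provides fold changes, normalization to the regular
pegRNA (= 1), exact/approximate one-tailed Wilcoxon signed-rank tests and
median/IQR summaries.

## Worked example

```python
import numpy as np
import spegkit as sk
from spegkit.seqcore import Interval, ReadingFrameAnnotation

rng = np.random.default_rng(7)
seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 250)))
seq[121] = "G"; seq[122] = "G"          # NGG PAM for a protospacer at [100, 120)
amplicon = "".join(seq)

target = sk.TargetSpec(amplicon, Interval(100, 120), "+")
frame = ReadingFrameAnnotation("+", 117, Interval(90, 180))
edit = sk.parse_edit_name(f"+5{target.pam_strand_base(5)}-to-T")

designs = sk.design_spegrnas(target, edit, frame)
for d in designs:
    print(d.name, "SSMs:", d.ssms)

amp = sk.AmpliconReference.from_design(target, edit, designs[0])
spec = sk.SimSpec({"unedited": 0.3, "intended_only": 0.25, "intended_plus_ssm": 0.15,
                   "ssm_only": 0.1, "unintended_indel": 0.1, "scaffold_byproduct": 0.1},
                  n_reads=2000, error_rate=0.0, seed=5)
reads, truth = sk.simulate_reads(amp, spec)
table = sk.quantify([(r.read_id, r.sequence) for r in reads], amp, min_depth=500)
for key, value in table.frequencies.items():
    print(f"{key}: {value:.3f}")
```

prints

```
speg_+5G-to-T_ssm3+6 SSMs: ((3, 'G', 'A'), (6, 'G', 'A'))
speg_+5G-to-T_ssm6 SSMs: ((6, 'G', 'A'),)
intended_edit: 0.400
unintended_indel: 0.100
incomplete_product: 0.100
byproduct: 0.100
```

The target is ORF1-phase, so the designer emits the dual scheme {3,6} first
and the single scheme {6} second; each SSM is the alphabetically smallest
synonymous base, evaluated on the codon *after* the intended edit is
applied. With error-free simulated reads the quantifier recovers every
simulated class proportion exactly: the intended-edit frequency 0.400 is
`intended_only + intended_plus_ssm`, and the SSM-only reads appear as
incomplete products.

The same functionality is exposed on the command line:

```sh
spegkit design   --ref amplicon.fa --protospacer GCGGAAGCGCAACTCCGTCG \
                 --edit +5G-to-T --frame-anchor 117 --coding-strand + --cds 90-180
spegkit scan     --spacer GCGGAAGCGCAACTCCGTCG --subject subject.fa --max-mm 5
spegkit simulate --ref amplicon.fa --target-config target.json \
                 --proportions '{"unedited":0.6,"intended_only":0.4}' \
                 --n 2000 --seed 1 --out reads.fq
spegkit quantify --ref amplicon.fa --target-config target.json --reads reads.fq
spegkit stats    --table pairs.tsv
```

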