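# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open, on the plus strand of the
reference. Nick-relative edit offsets are 1-based signed integers because
"+1" names the first base 3' of the nick on the protospacer (PAM) strand;
the conversion happens in one place (`TargetSpec.offset_to_index`). The
nick sits 3 nt 5' of the PAM, between protospacer positions 17 and 18 of a
20-mer — the standard SpCas9-H840A cut site. RTT position p (3' base = 1)
templates the PAM-strand base at nick offset +p, so edit names such as
"+5G-to-T" and SSM "position 5" share one coordinate system. Sequences are
DNA-alphabet throughout; RNA (U) appears only at serialization.

## The spegRNA rule

Same-sense mutations are restricted to the catalog {1}, {5}, {6}, {2,5},
{3,6}; positions 4, 7, 8 and 9 are never used because single substitutions
there do not improve editing. Which schemes are recommended follows from
the reading-frame register at the nick. The ORF phase labels are assigned
by requiring each phase's single recommended position to be a wobble
(third-codon) position: a wobble at offset +1 gives ORF2 (scheme {1}), at
+2 gives ORF3 ({2,5}, then {5}), at +3 gives ORF1 ({3,6}, then {6}). Dual
schemes are ranked before their single-position parents because two
additional substitutions gave the largest median gains. When `extended`
placement is enabled, the remaining catalog schemes are tried in the order
{2,5} > {5} > {3,6} > {6} > {1} (decreasing reported median fold gain,
1.90/1.62/1.41/1.32/1.28); they succeed only where the first or second
codon position is degenerate (Leu, Arg, Ser codons). The designer caps its
output at five designs and four same-sense substitutions per design.

Synonymy is always evaluated on the reference *carrying the intended
edit*, so the guarantee is: translating the CDS of the fully edited
reference (edit + SSMs) equals translating the CDS with the edit alone.
This matters when an SSM position shares a codon with the edit. The base
chosen at each position is the alphabetically smallest synonymous
alternative (as written on the coding strand): substitution type was found
immaterial, so a deterministic tie-break is preferred. Stop-codon-
preserving substitutions count as synonymous. Only the standard genetic
code is built in.

For indel edits combined with SSMs (aspegRNA), synonymy is computed on the
edited sequence with a shifted frame annotation, and only for in-frame
indels (length divisible by 3). Frameshifting indels or a missing frame
annotation yield the stabilized scaffold with no SSMs, plus a warning.

## Scaffold model

The default scaffold is the canonical 76-nt SpCas9 sgRNA backbone. Hairpin
geometry is explicit base-pair bookkeeping, not thermodynamic folding: the
small 3'-proximal hairpin is modelled as the 4-bp stem ACCG/CGGT (loop
AGT), listed bottom pair first. Its bottom pair is A/T, so apegRNA-2 —
replace the first non-C/G pair, bottom-up, with C (5') / G (3') — produces
a C/G pair at the bottom of the stem, changing exactly two bases.
apegRNA-1 inserts a C/G pair below the stem instead (+2 nt). Variants 3-5
need progressively more non-C/G pairs than the default stem offers and
raise a variant-undefined error unless a custom pair map is supplied; the
pair map is deliberately configuration-driven because published hairpin
diagrams differ between scaffold derivatives. Applying the same rewrite to
a scaffold with no 3' extension yields the stabilized sgRNA (asgRNA).

## Off-target scan

The scan is exhaustive and mismatch-only (no DNA/RNA bulges), mirroring
Cas-OFFinder settings: every position on both strands where the PAM
pattern matches (N = A/C/G/T only; N in the subject never matches) is
scored by Hamming distance over the spacer length; PAM mismatches gate the
site and are not counted. The default ceiling is 5 mismatches with a
strict NGG PAM.

## Read alignment

Reads are aligned semi-globally — read global, reference local — with
affine gap scoring: match +2, mismatch −4, gap open −6, gap extend −1 (a
length-g gap costs 6 + g). The kernel is a banded Gotoh dynamic program
(numba-compiled); the default band half-width of 24 columns around the
length-difference corridor comfortably covers the ≤ 8-nt events the
simulator produces and is checked against the unbanded optimum in the
tests. Indels are left-normalized after traceback (VCF-style shifting
through equal flanking bases), and window-membership tests consider every
score-equivalent placement of an event so that homopolymer ambiguity
cannot move an indel across the window boundary. Reads shorter than 30 nt
or scoring below 0 are excluded from all denominators; identity scores
2·length while unrelated sequence scores deeply negative, so the zero
threshold separates them cleanly.

## Outcome classification and frequencies

Per read, the classifier flags: the intended edit (substitution alleles
observed at their loci, or the exact normalized indel), each designed SSM,
unintended indels inside the quantification window, and scaffold
incorporation — an insertion of ≥ 3 nt within 5 nt of the nick matching
the reverse complement of the scaffold's 3'-terminal run of equal length
with ≤ 1 mismatch (all three thresholds configurable).

The quantification window runs from 8 nt upstream of the protospacer 5'
end to 52 nt downstream of its 3' end on the protospacer strand, so its
length is 8 + protospacer + 52 (80 bp at 20 nt) and the PAM falls inside
the downstream span. Denominators: substitution experiments use reads
covering the edit position; indel experiments use reads covering the nick
± 1 (the phrase "covering the target site" is ambiguous; one definition
each, fixed here). The substitution-frequency denominator keeps all
covering reads (only the numerator excludes indel-containing reads), and
positions with depth < 1000 are reported as missing.

Two classification choices deserve note. First, scaffold-incorporation
insertions are not counted as unintended indels — they set only the
byproduct flag; this keeps the outcome classes disjoint and makes the
simulator round trip exact (a read class is recovered as exactly one
frequency). Second, stray substitutions from sequencing error do not
contribute to any class flag (they appear only in the per-position
substitution matrix); otherwise a 10⁻³ error rate over a 250-bp read
would deterministically deflate the incomplete-product and byproduct
fractions by ~20% relative.

## Simulator

The simulator emulates single-end (R1-equivalent) amplicon reads of six
classes, each built by applying the class's events to the reference:
intended edit, designed SSMs, a random 1-3 nt indel inside the window for
the unintended class, or a 4-8 nt scaffold-tail insertion at the nick for
the byproduct class. The random indel is kept more than 5 nt away from the
nick so that it can never satisfy the scaffold detector — required for the
exact round-trip property. Class counts follow largest-remainder rounding;
substitution errors are uniform (each alternative base at rate e/3);
qualities are constant Q40, since quality modelling is not the point; and
a fixed seed makes the FASTQ byte-identical. The simulator does not model
cycle-dependent error profiles, PCR duplicates or paired ends, so passing
round-trip tests demonstrates the correctness of the frequency
definitions, not robustness to real-instrument artefacts.

## Statistics

One-tailed Wilcoxon signed-rank: zero differences are dropped before
ranking, ties get mid-ranks. With m ≤ 25 untied differences the p-value is
exact, computed from the full null distribution of the positive-rank sum
(the generating-polynomial recursion — identical to enumerating all 2^m
sign assignments); otherwise a normal approximation with tie and
continuity corrections is used, and both routes are cross-checked against
brute-force enumeration and an independent implementation in the tests.
The default alternative is "greater" (engineered guide > regular pegRNA),
matching how every comparison is oriented. p = P(W⁺ ≥ w_obs) at the
boundary, so an all-negative sample under "greater" gives p = 1. Quartiles
use linear interpolation. Fold-change flooring is off by default; a floor
of 0.01 (percentage points) documents how a control printed as 0.01%
yields arithmetic such as 49.76/0.01 = 4976. No multiple-testing
correction is applied.

## Problem sizes and defaults

Default PBS length 13 nt (valid range 1-17), default RTT length
max(13, edit 3' end + 6); both are exposed because published designs vary
them. Nicking-sgRNA candidates default to a 40-100 nt nick-to-nick window.
The test suite uses 250-bp synthetic amplicons; the randomized same-sense
guarantee runs 1000 targets per suite, the error-model round trip 50,000
reads at error 10⁻³, and the off-target oracle comparisons 10-kb subjects
— sizes chosen so the full suite completes in well under a minute while
every statistical check retains sub-percent resolution.

## Known limitations

No bulge-tolerant off-target search or activity scoring; no PAM-disrupting
silent-edit strategy; no epegRNA 3' structural motifs or chemical
modifications; no thermodynamic RNA folding (hairpin stability is pair
bookkeeping only); no paired-end merging, adapter trimming or quality
recalibration in the quantifier (a quality trim option exists but defaults
off for simulated reads). Experimental editing efficiencies measured in
cells are inputs to the statistics layer, not quantities this package can
recompute.
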