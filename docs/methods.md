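# Methods

This note documents the models and procedures implemented in
`strandscape`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Genome partition

The unit of analysis is an exhaustive, mutually exclusive labelling of
every genomic base into one of eight primary classes: rRNA, CDS, 5'UTR,
3'UTR, intron, 1-kb upstream flank, 1-kb downstream flank, intergenic.
Construction:

* **Isoform collapsing.** All transcripts of a gene are merged into a
  single model: exon union, CDS union, introns as the complement of the
  exon union within the gene span. This deliberately sacrifices isoform
  resolution for an unambiguous per-base labelling.
* **UTR inference.** Where UTR annotation is absent, exonic bases outside
  the CDS are 5'UTR if 5' of the CDS span and 3'UTR otherwise, relative
  to gene strand. Exons of a gene with no CDS at all are treated as
  3'UTR-like non-coding exonic sequence — a pragmatic default that keeps
  the partition exhaustive; such genes play no role in the coding-class
  statistics.
* **Precedence.** Where candidate regions overlap (e.g. a 1-kb flank
  reaching into a neighbour's exon), the class earlier in the order
  rRNA > CDS > 5'UTR > 3'UTR > intron > upstream > downstream wins, so
  coding signal is never diluted by neighbouring flanks or introns.
  Within one class, overlapping candidates from different genes are
  resolved by sorting on (start, end, gene id) — gene input order can
  never change the partition. Flanks are clipped at chromosome ends.
* **Repeat overlay.** Repeats are kept *separate from* the primary
  partition: they never puncture it. Each repeat carries its family
  label, its annotated strand, and a host class/gene determined by the
  majority of its bases (ties broken by class precedence). Reporting per
  host class keeps both views — "repeat" and "underlying primary class" —
  recoverable.
* **rRNA** is a primary class so that ribosomal read removal is an
  explicit, countable filter rather than an invisible preprocessing step.

Internal coordinates are 0-based half-open everywhere; GTF I/O converts
from 1-based inclusive at the boundary.

## Read filtering and assignment

A read is **unique** when its NH tag equals 1, falling back to a MAPQ
threshold (default 10) when no NH tag is present. Non-unique reads and
reads whose majority class is rRNA are dropped, with every drop reason
tallied so that `retained + dropped = input` is externally auditable.

Each retained read is assigned **once, never fractionally**:

* The repeat overlay is checked first: if strictly more than half of the
  aligned bases (the union of all blocks, for spliced reads) fall inside
  annotated repeats, the read is a repeat hit, attributed to the single
  repeat with most overlapping bases.
* Otherwise the majority primary class wins, ties broken by partition
  precedence; the owning gene is the one with most bases within the
  winning class.
* Orientation is *sense*/*antisense* against the owning feature's strand
  — the repeat's own annotated strand for overlay hits, which is what
  makes the family antisense/sense ratios meaningful — and raw
  plus/minus for intergenic reads, which have no feature strand.

## Landscape statistics

Per sample: `fraction[c] = reads_c / retained`; `density[c] = reads_c x
read_length / length(c)` (total class length, not covered length, as the
denominator); `covered_fraction[c]` from a per-base coverage bitmap;
`as_ratio[c] = antisense/sense`, reported as NaN (never infinity) when a
class has no sense reads.

**Two-condition testing.** The class proportion `(x, n)` is compared
between conditions with the two-sample test of equal proportions:
chi-square on the 2x2 table with Yates continuity correction, two-sided —
the documented default contract of the standard statistical tool for this
test. The test runs independently in each biological replicate pairing;
a shift is significant only when **every** replicate yields p < α
(default 0.05), and the reported p is the maximum across replicates.
This compound rule is deliberately conservative: under the null its flag
rate is roughly α² (verified empirically in the suite). No
multiple-testing correction is applied across the eight classes — the
replicate-concordance requirement is the error control here, and
consumers needing FDR control across many features should apply it
downstream.

Degenerate 2x2 tables (both counts zero, or both complements zero) carry
no evidence and return p = 1 rather than an error.

**Replicate correlation** is Pearson's r on `log(count + offset)`
(offset 1) over a feature-by-sample count matrix of per-gene sense
counts; constant vectors yield NaN.

## Repeat families

Family counts are normalised by each sample's total retained reads (the
scale cancels in every ratio). Fold changes are reported pooled
(`T2/T1`) and within each replicate (`A2/A1`, `B2/B1`); the antisense /
sense ratio is computed against the repeat's annotated strand per sample
and per pooled condition. A `Tot` row aggregates all families and equals
the family sums exactly. Intron-strand concordance is the fraction of
intron-hosted repeats whose strand matches the hosting gene's strand —
an annotation-level quantity with no sampling noise. Subfamily labels
can be merged into families through an explicit map (e.g. L1MA, L1MB →
L1); matching is otherwise exact.

## Splice junctions

A read with k+1 blocks contributes k junction observations, keyed by
(chromosome, donor, acceptor) = (end of upstream block, start of
downstream block). The per-side overhang is the length of the block
flanking the gap — the contiguous aligned stretch across the junction.

A junction is accepted within a condition (replicates pooled) when at
least `min_reads` (2) observations with distinct alignment starts each
have both overhangs ≥ `min_overhang` (15 nt). Distinct starts are our
reading of "independent reads": identical-start duplicates are likely
amplification artefacts. The 15-nt requirement is applied per read and
per side — the stricter, symmetric reading of an evidence rule that
could also be read as an aggregate; both knobs are configurable.
Acceptance is monotone in both thresholds.

Junction keys are strand-agnostic. A junction is **known** when donor
and acceptor exactly match one annotated intron of the same collapsed
gene; the fraction of annotated introns confirmed is reported alongside.
For classification, each side is labelled by the class of its flanking
aligned base (donor−1 and acceptor), with the repeat overlay taking
precedence; flank and rRNA classes fold into "Intergenic", giving six
side labels (3'UTR, 5'UTR, CDS, Intergenic, Intron, Repeat) whose sorted
pairs form the reported categories. Between conditions the accepted
novel junctions are partitioned into shared and exclusive sets, with a
category-percentage table per exclusive set.

## Transfrags

A transfrag is **intronic** (resp. **intergenic**) when strictly more
than 80% of its exonic bases — interval bases only, not the genomic span
of multi-exon fragments — lie in intron (resp. intergenic) primary
classes; anything else is "other". Repeat-overlay bases count toward
their host primary class here, since the question is *where* the
fragment lies, not *what* it overlaps. Expression is `overlapping reads
/ total length` per sample; a read touching several transfrags counts
toward each (transfrags are an overlay, not a partition). Differential
expression of the resulting count matrix is out of scope; the matrix is
emitted for standard count-based DE tools.

## Synthetic data generator

The generator emulates the study conditions: two conditions x two
biological replicates, stranded single-end 50-nt error-free reads over a
260-kb two-chromosome toy genome with 14 protein-coding genes (one
multi-isoform, two single-exon, several with multi-kb introns, one pair
800 bp apart to exercise flank collisions), one rRNA gene, and 91 L1/L2
repeats — 75 intronic (L1 planted at 34% strand concordance with the
hosting gene, L2 at 44%) and 16 intergenic, on both strands.

Baseline composition (fraction of reads per class): CDS 0.355, 5'UTR
0.02, 3'UTR 0.045, intron 0.14, flanks 0.05 each, intergenic 0.27,
repeats 0.07; the stress condition overrides CDS→0.30, intron→0.18,
repeats→0.085. These three overrides are *zero-sum*, so untouched
classes keep their exact baseline fraction and serve as negative
controls for the proportion test. Antisense probabilities: 0.01 in CDS
(99% sense coding transcription), 0.02 in UTRs, 0.25 in introns, 0.30 in
flanks; repeat reads are drawn with family weights L1 0.66 / L2 0.34 and
per-family antisense probabilities 0.75 (L1, i.e. a 3:1
antisense-dominated family) and 0.43 (L2, sense-leaning). Overrides
that leave the simplex are rejected unless renormalisation of the
untouched classes is explicitly requested — silent renormalisation would
corrupt the planted truth.

Reads are drawn class → interval (length-weighted, repeat-free for
primary classes so every bulk placement is class-pure) → uniform integer
start → orientation by the class/family antisense probability. On top
of the bulk draw the generator plants: junction reads (100 shared, 40
T1-exclusive and 60 T2-exclusive novel junctions, support 3 with 20-nt+
overhangs and distinct starts, across six region-pair site templates;
plus 20 decoys — single-read or 14-nt-overhang — that must be rejected;
plus spliced support for 60% of annotated introns), deliberate
boundary-straddling reads at a configurable rate, rRNA reads and NH=2
multimappers to exercise the filters, and 30 intronic / 20 intergenic /
5 boundary transfrags.

All placement arithmetic is integer-based and seeded, so identical seeds
give byte-identical SAM/GTF/BED output. The design bundle carries a
manifest of every expected statistic with a tolerance: binomial 99%
bounds for sampled fractions (with the exact contribution of planted
reads folded in), delta-method bounds for ratios, and exact counts for
annotation-level quantities.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: sequence content and
alignment errors (uniqueness is simulated via NH tags, not real
multimapping), colour-space artefacts of the original platform, PCR
duplicates, coverage biases along transcripts (e.g. 3' enrichment of
poly-A libraries), overlapping genes on opposite strands, fractional or
ambiguous feature overlaps beyond simple boundary straddling, and
biological replicate variance beyond multinomial sampling (real
replicates are overdispersed; the concordance rule is *more* valuable
there, not less).

## Problem sizes and numerical choices

The validation suite runs the full design at 50,000 reads per sample
(~200k reads per design) — large enough that the planted shifts are
detected with z ≈ 8–19 while the whole suite stays fast; the recovery
test for repeat families uses a repeat fraction of 0.40, i.e. 20,000
repeat-derived reads per baseline sample. Majority ties (exactly half
the bases) fall to the higher-precedence class; the repeat overlay wins
only on a strict majority. Report floats are written with six
significant digits and JSON keys sorted, making reruns byte-identical
and diffable.

## Known limitations

* One assignment per read means features sharing bases (e.g. a repeat
  inside an exon) compete by majority; per-feature multi-counting is not
  offered.
* The partition resolves overlapping same-class annotation
  deterministically but arbitrarily (first by coordinate, then gene id);
  dense overlapping gene clusters would deserve a richer ownership model.
* Junction classification looks at single flanking bases; a junction
  whose flank sits exactly on a class boundary inherits that base's
  class.
* The chi-square proportion test is asymptotic; for very small class
  counts an exact test would be preferable (the synthetic designs keep
  counts far from that regime).
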