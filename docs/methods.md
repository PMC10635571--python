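# Methods

## Overview

The package analyses proximity-ligation CLIP libraries downstream of read
alignment.  The unit of evidence is the chimeric read: two aligned arms,
one ligation event.  Intramolecular chimeras (both arms in one gene) carry
RNA secondary-structure information and are clustered into duplex groups;
intermolecular chimeras (arms in two genes) carry trans-interaction
information and are tested against a random-ligation null.  All stages are
deterministic given a seed.

## Coordinates and input conventions

Internal coordinates are 0-based half-open everywhere.  GTF is read and
written 1-based closed; SAM positions are converted by pysam at the
boundary.  Gene assignment of an arm uses the arm midpoint on the matching
strand; when genes nest, the smaller span wins, then the lexicographically
smaller gene id.  The assignment rule is a package choice — upstream
protocols do not state one — and it is deterministic and total over
annotated positions.

Biotypes collapse onto six classes (mRNA, lncRNA, snRNA, snoRNA,
pseudogene, other) through a configurable table; `*_pseudogene` variants
all map to pseudogene and unknown biotypes to other, so the mapping is
total.

## Chimera extraction

1. Optional contig exclusion (e.g. an rRNA contig) before any other
   filter, standing in for a separate pre-alignment step.
2. Quality filter: records with MAPQ < 30 or the secondary flag are
   dropped; a chimeric read survives only if **both** segments pass.
3. PCR-duplicate removal: among fragments whose full coordinate tuple
   (contig, strand, block list, over all segments) is identical, the
   lexicographically smallest read id is kept.  The rule is idempotent.
4. Gapped reads are splice-derived iff **every** N-gap equals an annotated
   intron exactly (same contig, strand, donor, acceptor); splice reads are
   discarded from the chimera set (they still count toward arm coverage).
   Any other gapped read is structural: its arms are the merged blocks on
   each side of the largest gap, 5′ arm first in read orientation.
5. Chimerically mapped reads contribute their primary segment as the 5′
   arm and the supplementary segment as the 3′ arm.
6. Paired-end mates are one fragment: same-contig same-strand mates merge
   their block lists (overlapping/abutting blocks coalesce; a residual
   inner gap is classified like any other gap), mates on different contigs
   or strands are treated as chimeric segments.  Reads with more than two
   segments after filtering are skipped and counted.

Scope labels partition the chimera set: intra (same assigned gene), inter
(two genes), unassigned (either arm intergenic).  Unassigned chimeras are
excluded from gene-level stages but retained in contact exports.

## Duplex groups

Within a gene, each chimera's arms are put in genomic order (left arm = A);
chimeras whose arms overlap each other are excluded as circular artifacts.
Two chimeras join when their A arms overlap by ≥ 1 bp AND their B arms
overlap by ≥ 1 bp; duplex groups are the connected components of this
graph.  The implementation sorts by A-arm start and sweeps (the inner loop
stops at the first non-overlapping A arm, which enumerates exactly the
A-overlapping pairs); tests compare the resulting partition against an
explicit all-pairs graph built with networkx.

A group is reported only with at least two members whose terminus
4-tuples (A.start, A.end, B.start, B.end) differ — "unique reads with
different termini".  Consensus arms are the unions of member arms.

The connection score is coverage_AB / √(coverage_A · coverage_B), with
coverage_AB = number of member chimeras after deduplication and
coverage_A/B = number of distinct fragments (non-chimeric reads, splice
reads and chimera arms) overlapping the consensus arm by ≥ 1 bp on the
matching strand.  The per-fragment counting choice (rather than per-base
mean depth) is a package decision; the coverage function is a small,
replaceable component.  Note the score is invariant under common scaling
of all three coverages and linear in the numerator alone.  Groups are kept
when score > 0.01 — strictly, so a score of exactly 0.01 is removed.

## Intermolecular interactions

Gene-pair contact counts are order-normalised and conserve the number of
inter chimeras.  The null model permutes the 3′-arm gene labels against
the 5′-arm labels; every gene's arm count is preserved exactly in every
iteration, so each gene's own ligation propensity — its expression — is
its local background.  The empirical upper-tail P uses the add-one
correction p = (1 + #{null ≥ obs}) / (1 + n_iter) and never returns 0.
No multiple-testing correction is applied; the downstream filter is
p < 0.05, strict.

Every observed pair receives a P value; the ≥ 2-supporting-read
requirement (mirroring the duplex rule, configurable) applies only in the
final significance call.  This split matters: computing P only for pairs
already at ≥ 2 contacts conditions the tested set on sitting in the upper
tail of its own discrete null, and the fraction of tested pairs below any
nominal α then exceeds α substantially (≈ 0.10 at α = 0.05 in
pure-background simulations).  With P computed for all observed pairs the
procedure is calibrated (≈ 0.05) while the significant set still requires
two reads.

Permutation counting is vectorised: pair keys are sorted per iteration and
tested-pair counts read off with binary search; 1000 iterations over 20k
chimeras and ~10k pairs take a few seconds.

## Exports

`.short` rows are `str1 chr1 pos1 frag1 str2 chr2 pos2 frag2` with strand
0 = forward, 1 = reverse, pos = the arm's 5′-most aligned base (1-based),
sides ordered by (contig, position) and rows sorted by chromosome names —
the sort the downstream `pre` command requires.  frag1/frag2 are fixed to
0/1 so same-position rows remain distinct.  A strict re-parser enforces
the grammar and the sorting invariant.

Class-pair distributions count unordered biotype-class pairs over
class-assigned inter chimeras; fractions sum to 1 and the denominator
excludes unassigned chimeras (reported alongside raw counts).  Heatmap
matrices hold raw contact counts with a log10 display transform masking
zeros.  Interaction-set overlap uses midpoint containment for site
matching and an upper-tail hypergeometric P
(`scipy.stats.hypergeom.sf`); the universe size is an explicit parameter
because no canonical universe exists for interaction sites.

## Splicing overlap

Events come from a MISO-style TSV with explicit exon/intron parts.  The
significance filters are all inclusive: n_inc ≥ 1, n_exc ≥ 1,
n_inc + n_exc ≥ 10, |ΔΨ| ≥ 0.20, Bayes factor ≥ 10.  An event is bound
when a significant inter-chimera arm overlaps one of its parts by ≥ 1 bp,
that arm's assigned gene equals the event's host gene (a declared,
switchable requirement), and the partner gene's class is in the ncRNA set
{lncRNA, snRNA, snoRNA} (pseudogenes excluded by default, configurable).
Unbound events report the nearest ncRNA-partnered arm and its distance to
the event span.  Counting is event-level: an event bound by several
ncRNAs of one class counts once for that class.

## Synthetic data

The generator works at alignment level — no sequences, no aligner —
because the pipeline starts downstream of mapping.  It emits, per seed:

* a single-contig annotation with non-overlapping multi-exon genes
  (2–5 exons of 120–400 bp, introns 100–400 bp) across the six biotype
  classes (defaults 40/12/4/4/2/2);
* log-normal expression weights (µ = 0, σ = 1) driving every
  expression-weighted draw;
* non-chimeric exonic reads (30–60 bp) and splice-junction gapped reads
  whose gap is exactly an annotated intron;
* planted duplexes: arms of 25 bp placed ≥ 8 bp inside two exons of one
  gene; each support jitters all four termini by ±0–5 bp with distinct
  tuples enforced, so deduplication never collapses planted support and a
  gap-encoded chimera's gap can never coincide with an annotated intron;
* intramolecular chimeras encoded half as two-segment chimeric alignments
  and half as single gapped alignments (configurable mix), matching the
  two chimera sources in real libraries;
* background chimeras by degree-preserving random ligation (both arm
  genes drawn independently ∝ expression).  `n_chimeric_reads`, when set,
  is the background count; otherwise it is derived from
  `background_ligation_rate` as rate/(1−rate) × planted-chimera count, so
  the rate is the background fraction of all chimeras.  Background splits
  50/50 intra/trans by default;
* planted trans pairs: for enrichment factor f, round((f−1) × expected
  background contacts) extra chimeras, so the pair's total is ~f× its
  random-ligation expectation;
* exact-coordinate PCR duplicates (per-read Bernoulli at duplicate_rate)
  and low-MAPQ decoys (MAPQ 10 vs 60 for normal reads; the pipeline's
  filter threshold is 30), alternating non-chimeric and chimeric forms.

The truth table maps every read id to its generating mechanism.  What the
simulator does **not** model: sequence content and mapping ambiguity,
alignment soft-clipping, arm-length and jitter distributions estimated
from real libraries, overlapping genes, multi-transcript genes, and
ligation biases beyond expression.  Passing tests therefore demonstrate
the correctness of the record-level logic and the statistical calibration
of the null under its own assumptions — not robustness to alignment
artifacts in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of each
analysis, chosen to exercise the asymptotics that matter: a ~52k-read
library for extraction exactness; 100 random instances of ≤ 50 chimeras
for clustering-oracle equivalence; 50 planted duplexes at 5 supports over
5% background for recovery; five pure-background runs of 200 genes and
20k inter chimeras at 1000 null iterations for calibration; twenty
planted-pair runs (3000 background chimeras, enrichment 10×, expected
contacts ≥ 10) for power.  Empirical P values are add-one corrected;
score and P cutoffs are strict inequalities; ties in gene assignment
break by span then id; degenerate inputs (empty chimera sets, single-gene
nulls, empty interaction tables) produce empty but valid outputs.

## Known limitations

* Gene-level (not site-level) trans interactions; no sub-gene binning.
* The coverage definition entering the connection score is one of several
  defensible readings of "read coverage"; scores shift monotonically but
  rankings are stable under the alternatives we examined.
* The null conditions on per-gene arm totals only; ligation-distance or
  compartment effects would need a richer null.
* Multi-gap reads use the largest gap; minor gaps are absorbed into arms.
* No FDR control across the pair universe — by design, matching the
  stated p < 0.05 usage.
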