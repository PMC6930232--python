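# Methods

## The detection model

`ripscan` detects non-reference LTR-retrotransposon insertions from
paired-end evidence. A sequencing fragment that straddles the junction of
an insertion yields a pair in which one mate carries element sequence and
the other carries unique flanking genome. The scan therefore retains a
pair exactly when **one** mate hits the TE family library and the other
maps **uniquely** to the reference; the unique mate's leftmost aligned
base is the anchor. Both junctions of an insertion at reference position
*p* anchor within a fragment length of *p* (the right-hand flank maps back
to *p* because insertions are absent from the reference coordinate
system), so anchors from one event concentrate in one 10 kb window.

Two thresholds operate on the windowed counts and are deliberately kept
distinct, because they are defined differently:

* **call rule**: a `(family, chrom, window)` locus is called when it has
  **more than three** supporting pairs (`call_min_reads = 4`);
* **copy-number rule**: an accession's per-family copy number counts
  windows with **at least three** supporting pairs (`copy_min_reads = 3`).

Loci are family-distinct: two families calling the same window are two
loci. The representative insertion point of a locus is the lower median of
its anchor positions — window indices alone cannot support bp-scale
statistics such as mean TSS distance, so every genomic-context statistic
consumes this point (a window-midpoint mode is available by flag).

## TE-hit definition and the built-in mapper

"Mapped to the TE library" accepts **any** hit, unique or not: LTR
families are internally repetitive and near-identical between members, so
requiring uniqueness there would discard essentially all TE mates. The
hit test also accepts one-end-clipped (local, ungapped) matches with at
least `min_te_aligned = 30` aligned bases at ≤ 5 % mismatches. This
mirrors what a soft-clipping aligner reports for junction-spanning mates
and roughly doubles the usable evidence per insertion; with an
end-to-end-only rule, a 5X cohort leaves ~5 expected full-length evidence
pairs per junction pair, too few to clear the >3-read call rule reliably.
Genomic anchoring is stricter: full-length, ungapped, ≤ 5 % mismatches,
and the best locus must beat the runner-up by ≥ 2 mismatches to count as
unique.

The mapper is a canonical k-mer seed index (k = 31 for the genome, k = 17
for the shorter, diverged TE members) with vote-based candidate loci and
ungapped extension. It is deliberately indel-free: the read simulator
emits substitution errors only, and real data is expected to arrive
through the SAM import path (`import_sam_evidence`), which applies the
same retention logic to external alignments with a primary-alignment,
MAPQ ≥ 20 uniqueness rule (the conventional cutoff, exposed as a flag).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not maize biology:

* an i.i.d. 50 % GC reference genome (default one 2 Mb chromosome) with
  full-length TE copies planted at annotated positions (default 3
  families × 25 copies of 5 kb), each copy carrying 1 % divergence from
  its family prototype so members are non-identical;
* three accession groups (teosinte / landrace / improved, 4 accessions
  each by default) whose donor genomes carry literal insertions of
  diverged family copies drawn from nested pools — shared (10),
  group-specific (teosinte 15 / landrace 30 / improved 5) and private per
  accession (5). The landrace > teosinte > improved asymmetry is driven
  entirely by the pool sizes;
* paired reads at 5X with 2×100 bp mates, Normal(300, 30) fragments and
  0.5 % substitution error, exactly
  `⌊coverage × genome / (2 × read length)⌋` pairs per accession,
  deterministic given `(seed, accession)`.

Three placement rules make the truth table identifiable at window
resolution, all fixed as generator defaults: insertion sites sit ≥ 2×
fragment length apart, ≥ 2.5 kb from any reference copy (so a ±2 kb
validation region never contains an unrelated element), and at least a
window (11.5 kb) away from **same-family** reference copies (so a
polymorphic locus never shares a `(family, window)` with a
reference-resident element). Pool loci cycle through families rather than
being drawn i.i.d., so each family carries every pool's signal — the
condition under which per-family group comparisons are meaningful at desk
scale.

Truth positions are recorded in reference coordinates, the system all
calls are made in, so recovery tests need no lift-over. Not modelled:
indels, base-quality profiles, target-site duplications, nested or
heterozygous insertions (accessions are homozygous, matching
presence/absence calling), GC bias, and real TE sequence structure.
Passing tests demonstrate the pipeline's logic and its behaviour under
substitution noise and family divergence; they do not measure performance
on real repeat landscapes.

## Reference-resident elements and masking

Every donor genome carries the reference's own TE copies, and reads
spanning their junctions legitimately satisfy the discordant criterion,
so each accession calls the annotated copies as well. These are genuine
presences, not errors, but they are shared by construction and carry no
population signal. `mask_reference_windows` removes same-family windows
overlapping annotated copies (padded by 300 bp, the scale over which
anchors scatter). The RIP matrix, frequency statistics, PCA and the
recovery precision are computed on masked calls; per-family group
copy-number comparisons also use the polymorphic (masked) counts, since
in the synthetic design the unmasked baseline is identical-mean counting
noise across groups. Unmasked counts remain the default for the
`copy_number` operation itself and are available everywhere by flag; on
real data, where reference TE content genuinely varies, masking is the
user's choice (`--mask-bed`).

## Population statistics and structure

Group RIP sets use union semantics (a locus belongs to a group if any
member carries it). Venn partitioning is the standard 7-region disjoint
decomposition, checked exactly against brute-force enumeration. Insertion
frequency is carriers/group-size; per-family mean frequency averages over
the group's detected loci by default (`--freq-denominator` switches to
cohort-detected loci). The "common RIP" rule is strict (> 0.2). Group
distribution comparisons default to the two-sided Wilcoxon rank-sum
(exact for tie-free samples ≤ 40 observations), robust for the skewed
copy-number distributions involved; Welch's t-test is available by flag
and is the default for TSS-distance comparisons.

PCA encodes presence as homozygous dosage (0/2) — what a ped-file
conversion of dominant markers produces — drops monomorphic loci
(required by the standardization), forms the GCTA-convention GRM
`A = WWᵀ/m`, and takes the top eigenpairs. Coordinates are
`eigenvector × √eigenvalue`; each eigenvector's largest-magnitude entry
is made positive for determinism, and a flat spectrum (e.g. an identity
GRM) sets a `degenerate` flag. A `.ped/.map` export supports external
cross-checking.

## Validation against an independent assembly

For each supporting pair of a called locus, the genomic mate is mapped
uniquely to the alternate assembly and the TE mate is searched,
mismatch-tolerantly (≤ 5 %) on both strands, within ±2 kb of that
position. The validated fraction over all tested pairs is the score: an
assembly that carries the insertions validates ~100 % of pairs, while the
insertion-free reference validates ~0 % of polymorphic calls. Pairs whose
anchor cannot be located count as tested-and-failed (conservative).

## Numerical and design choices

* Windows are fixed non-overlapping tiles anchored at coordinate 0; no
  sliding.
* Lower median breaks insertion-point ties deterministically.
* The metagene profile bins each anchor by genomic layout (fixed-width
  40+40 flank bins of 50 bp, 100 body bins) and flips the bin index for
  minus-strand genes, which makes a global strand flip reverse the
  profile exactly — an invariant the tests assert bitwise.
* Feature classification precedence is exon > intron > up2kb > down2kb >
  intergenic, strand-aware flanks.
* Upstream-enrichment depths are normalized per accession before the
  ≥ 5 ratio (unequal group sizes would otherwise bias the screen), with a
  one-read pseudocount in the denominator group.
* 1 Mb density correlation is Pearson on per-bin insertion counts vs.
  gene-start counts; zero-variance vectors return null with a warning.
* All randomness flows from one integer seed; per-accession streams are
  salted by CRC32 of the accession name, so generation order is
  irrelevant.

## Problem sizes

The standard desk-scale study analysed by `scripts/acceptance.py` and the
end-to-end tests is the generator's default: 12 accessions on a 2 Mb
chromosome at 5X, ~54,000 pairs per accession, ~360 true insertion events
cohort-wide. This size gives every locus an expected 8–9 supporting
pairs — enough that the >3-read rule operates in its intended regime —
while one full analysis completes in about a minute on one CPU. Unit
tests use a 300 kb / 6-accession cohort.

## Known limitations

* The built-in mapper has no gapped alignment; indel-bearing reads are
  lost (irrelevant for the simulator, real data should use the SAM path).
* Breakpoints are window/median-resolution, not bp-resolution; no
  split-read refinement.
* No zygosity model; presence/absence only.
* With small groups every detected locus has frequency ≥ 1/group-size, so
  common-RIP fractions saturate near 1.0 at desk scale; the statistic
  discriminates only for larger cohorts.
* Gene-ontology enrichment of enriched gene lists is out of scope (the
  TSV gene list is the final output).
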