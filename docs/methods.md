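# Methods

This note documents the models and procedures implemented in `phasiclust`,
the parameter defaults and why they hold, the design choices made where the
procedure was genuinely open, and the limits of what the synthetic data can
show.

## Scope and data model

The pipeline consumes genome-aligned small-RNA reads (SAM/BAM, or a BED6
table with the read length in the name column), a genome FASTA, a GFF3 gene
annotation (gene + exon features; introns derived), and a gene × sample
mRNA TPM table. Internally every coordinate is 0-based half-open; GFF3's
1-based inclusive convention is converted only at the I/O boundary, so
interval arithmetic carries no off-by-one ambiguity. Reads keep their
placement, length, strand, mismatch count (SAM `NM`, 0 if absent) and
placement count (`NH`, 1 if absent).

Read retention follows the biology of the system: reads shorter than 21 nt
are treated as degradation products and dropped, reads longer than 25 nt
exceed the Dicer product range, only error-free alignments are kept, and
reads with more than 100 placements are discarded. Libraries are
downsampled without replacement to the size of the smallest before any
cross-sample comparison (cluster calling, phasing), so detection thresholds
mean the same thing in every sample.

## Cluster calling and unification

An SRC is a maximal run of covered positions (an *island*), pad-merged and
coverage-filtered:

1. islands = maximal runs of genome positions covered by ≥ 1 read;
2. islands separated by an uncovered gap < `pad` (default 100 bp) merge;
3. merged islands with total alignment count ≥ `mincov` (default 20)
   are emitted, with coordinates spanning their reads.

`mincov` counts *alignments per cluster*, not per-base depth; a per-base
depth mode exists behind `mincov_mode="depth"` for comparisons with
depth-threshold callers. The merge comparison is strict (`gap < pad`),
with an inclusive option. The seed → pad-merge → filter order is fixed:
filtering before merging would delete sub-threshold islands that
legitimately bridge into one cluster. Per-sample cluster sets are unified
with mergeBed-default semantics: overlapping *or book-ended* intervals
merge, so unified SRCs are pairwise separated by ≥ 1 bp. Both operations
are verified in the test suite against a brute-force per-base-coverage
oracle on random libraries.

Multi-mapping: cluster calling takes one placement per read as given in
the input (the primary alignment); quantification counts all retained
placements, weighted 1/NH by default (unweighted mode available). This
trades the probabilistic multi-mapper placement of ShortStack-style
callers for exact reproducibility; both counting behaviours are exposed.

## Boundary modification

SRC boundaries from coverage alone can spill across gene limits or span
several genes, producing spurious gene associations. Per gene–SRC pair
with gene fraction covered *g* and SRC fraction covered *s*:

| condition            | action  | effect                                   |
|----------------------|---------|------------------------------------------|
| g > 0.8 and s ≥ 0.2  | trim    | SRC interval := SRC ∩ gene               |
| g ≥ 0.1 and s > 0.8  | retain  | SRC kept unchanged for this gene         |
| otherwise            | discard | pair excluded from gene association      |

Inequality strictness is honoured exactly as stated above; when both rules
fire (g > 0.8 and s > 0.8) the trim rule takes precedence — trimming is
then a no-op or a strict improvement in specificity, whereas retaining
would keep a boundary already known to overhang. One modified SRC is
emitted per non-discard pair (ids suffixed with the gene id when one SRC
serves several genes), because the trimmed intervals must be requantified
per gene association. Trimming never extends an interval, and re-running
the rules on trimmed output only yields trim fixed points or retains.
SRCs overlapping no gene drop out of gene-level analyses.

## Quantification

Two per-million measures are computed per SRC and sample:

* `tpm` (default for thresholds): `(count / length_kb) · 1e6 / Σ_j
  (count_j / length_j_kb)` — length-normalised, sums to 1e6 per sample;
* `scaled_count`: `count · 1e6 / (total_aligned − exclusion_counts)`,
  where `exclusion_counts` removes reads attributable to exogenous feeding
  constructs before the scale factor is formed (0 for endogenous-only
  runs).

Both are always reported because "per-million" thresholds in this
literature do not always state length normalisation; analyses record which
variant they used (`tpm_variant` mode). SRCs with TPM strictly greater
than 1 in a serotype are that serotype's *serotype-specific* set.

The *dicer call* of a cluster is its modal read length over 21–25 nt if
that mode holds at least a dominance fraction (default 0.8) of the mass
and is unique; otherwise `N`. The dominance value is a conventional
dominant-fraction choice exposed in config; the call is invariant to
uniform scaling of the histogram.

**Exon–exon junctions versus introns.** Small RNAs matching a spliced
junction must derive from mature mRNA — a contiguous genome alignment
cannot cross an intron. Each junction's reference is the last 18 nt of the
upstream exon concatenated with the first 18 nt of the downstream exon
(36 nt); a read is assigned to the junction iff its sequence (or reverse
complement) matches the template with 0 mismatches while spanning the
splice point by ≥ 1 nt on each side. Exons shorter than the flank truncate
it with a warning. A genomic-window fallback mode counts reads overlapping
the 36-nt window around the splice site instead. Intron counts are plain
placement overlaps with intron intervals.

## Phasing detection

The phase score for a window/register with phased abundance P, unphased
abundance U and k distinct occupied phased positions (both strands pooled,
11 per strand, 22 possible) is

    score(P, U, k) = (k − 2) · ln(1 + 10 · P / (1 + U)),  and 0 for k ≤ 2.

The exponent rewards the number of occupied cycles: fewer than three
occupied phased positions carry no evidence of periodicity, hence the hard
zero. The score is strictly increasing in P and k and strictly decreasing
in U (for k ≥ 3, P > 0).

Windows are 11 cycles of 23 nt (253 bp), anchored at every genomic
position holding a read 5′ end; a dense per-base scan mode exists and
yields the same pass/fail set at far higher cost, because a window with no
read at its left edge is dominated by the window anchored at its first
read. Per window the register maximising the score is chosen (ties toward
the smaller register index — an arbitrary but fixed convention). A window
passes iff score > 10 AND ≥ 3 distinct occupied phased bins *per strand*
AND ≥ 20 reads in total. Passing windows merge into phased regions at
< 100 bp separation, keeping the best score.

Minus-strand reads are mapped into registers through a +2 nt offset — the
2-nt 3′ overhang Dicer leaves between the strands of one duplex — so both
strands of a phased locus share a register. The offset is configurable
(0–3) since overhang conventions differ between tools. Abundances are read
counts (optionally 1/NH-weighted); k counts distinct occupied positions,
not reads.

The per-strand bin criterion and the 20-read floor are enforced exactly:
a locus phased on one strand only, or a 19-read perfectly phased locus, is
always rejected (both are pinned in tests). On planted phased loci with
≥ 5 cycles, ≥ 40 reads and both strands populated, detection sensitivity
is ≥ 95 % with a region-level false-positive rate < 5 % on matched
unphased loci (measured over 200 seeded simulations in the acceptance
suite; at these depths both rates are in practice 100 % / 0 %).

## Integration

* **GSRCs**: genes with ≥ 1 non-discard SRC link in *every* serotype
  (links restricted to each serotype's serotype-specific SRCs); presence
  per serotype is kept for set-intersection (UpSet-style) counts.
* **Coverage classes**: percent of the gene body covered by the union of
  its SRC intersections; class I ≤ 46 % < class II ≤ 88 % < class III.
  The middle class is read as 46 % < cov ≤ 88 %, the only interpretation
  giving three disjoint, exhaustive classes.
* **Correlation**: per gene, Pearson r between summed sRNA accumulation of
  its linked SRCs and its mRNA TPM across paired samples (a gene linked to
  several SRCs sums them; an SRC linked to several genes contributes fully
  to each). Two-sided p from the t-transform (n − 2 df), BH correction
  across genes, sign called only at q < 0.05. Correlation runs on the
  natural TPM scale by default with a log2(x+1) mode; the mode is logged,
  since published analyses often plot log scale without stating the
  correlation scale. Zero-variance genes are flagged and reported `ns`.
* **Mutant contrast**: median-of-ratios size factors over all samples,
  per-locus `log2((mean_mut + 1) / (mean_wt + 1))`, phased versus unphased
  compared by two-sided Wilcoxon rank-sum. The pseudocount of 1 normalised
  count is a simple documented substitute for shrinkage estimators;
  externally computed differential-expression tables can be imported
  instead. Note that when a large fraction of loci is depleted, the size
  factors absorb part of the global shift, moving unphased medians
  slightly positive — the phased-versus-unphased *difference* is the
  meaningful quantity.
* **Enrichment**: one-sided hypergeometric upper-tail p for
  over-representation of phased loci among class III GSRCs.

## Synthetic data

The generator plants known structure so every stage has ground truth:

* genomes of random sequence with non-overlapping multi-exon genes
  (exons ≥ 60 bp, introns ≥ 20 bp, intergenic gaps ≥ 200 bp — the compact
  architecture of a ciliate macronuclear genome);
* read lengths 21–25 nt with a 23-nt mode (default mass 0.50 at 23);
* phased loci: plus-strand 5′ ends on `start + 23c + offset`, minus-strand
  5′ ends on the same grid +2 nt; unphased loci draw 5′ ends uniformly;
  counts are Poisson(mean × per-sample multiplier), thinned by the
  mutant-depletion fraction in rdr1/rdr2 samples;
* background "degradation-like" reads scattered genome-wide (default
  0.5 reads/kb) with the same length distribution — the 21-nt analysis
  floor already models the exclusion of shorter degradation products;
* mRNA tables: lognormal baselines × per-serotype factors × replicate
  noise, with genes under depleted phased clusters multiplied by a
  derepression factor (default 1.5) in mutant samples;
* sense fractions default to 0.5 for phased loci and uniform 0.3–0.7 for
  unphased ones — placeholders reflecting the absence of strand bias in
  this system, not measured values.

The default study (`simulate_study`) uses two 50-kb chromosomes, 24
three-exon genes and 18 loci: 6 phased clusters spanning entire gene
bodies (depleted 60 % in mutants), 6 unphased universal clusters covering
15–45 % of their genes, 4 serotype-private clusters and 2 intergenic ones,
sequenced as 4 WT serotypes × 2 replicates plus rdr1/rdr2 × 2. The
mutant-contrast acceptance check runs at the count level (Poisson counts
with planted depletion/derepression, 50 loci per group, 3 replicates),
since that criterion concerns the normalisation/fold-change/test machinery
rather than read placement.

What the synthetic data do **not** emulate: sequencing errors and quality
profiles (the pipeline consumes alignments), genuine multi-mapping
ambiguity (all simulated reads are unique placements; the 1/NH weighting
path is tested with constructed multi-mappers), true ShortStack-style
probabilistic placement, repeat structure, and the scale of a real
macronuclear genome. Passing tests therefore demonstrate correctness of
the statistical and interval machinery under the stated model, not
robustness to alignment artefacts in real libraries.

## Numerical and engineering choices

* Problem sizes in tests and the acceptance script (10-kb toy chromosomes,
  hundreds of reads per library, 100–200 simulation rounds) are chosen so
  the full suite completes in well under a minute while keeping binomial /
  Poisson sampling error far from the asserted margins.
* The P-score is computed as `(k−2)·log1p(10P/(1+U))`; tests compare it to
  an independently expanded `(k−2)·ln(1+10P/(1+U))` at 1e−12.
* TPM conservation (Σ = 1e6 per sample) is asserted at 1e−6 relative.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  fixture files are byte-identical under a fixed seed, and `run_all`
  reruns are bit-identical (the manifest records versions, seed, a
  parameter hash and input checksums, deliberately no timestamps).
* Degenerate inputs: empty libraries yield empty results (with a warning
  on load); zero-variance correlation vectors and all-zero contrast loci
  are flagged, never silently dropped; infeasible genome packing and
  out-of-bounds loci raise with the violated constraint named.

## Known limitations

* Cluster calling uses primary placements only; a heavily multi-mapped
  locus can fall below `mincov` that a probabilistic placer would rescue.
* The EEJ template match requires read sequences; libraries loaded without
  sequences can only use the genomic-window fallback.
* The pseudocount fold-change is biased toward zero for low-count loci
  relative to shrinkage-based estimators.
* Correlation analysis assumes the paired sample layout (serotypes ×
  replicates) and does not model replicate covariance.
* P-score detection with cycle lengths other than 23 is supported
  (`cycle` parameter) but only the 23-nt default is exercised by the
  planted-truth acceptance checks.
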