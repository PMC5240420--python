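# Methods

## Reference model

Quantification is done at the level of distinct mature miRNA sequences, not
genes: when several genes emit an identical mature sequence, sequencing
cannot attribute a read to a gene, so the sequence becomes a single target
whose `member_genes` column carries every matching gene. The target is
named after the lexicographically first member — any fixed rule works, and
this one is deterministic and locale-independent.

Hairpin (precursor) sequences are kept as separate targets with every
occurrence of their *own* annotated mature products replaced by `N`
(substring search; annotation coordinates are not present in FASTA input).
Masking is restricted to a hairpin's own children: masking every mature
everywhere would erase legitimately shared subsequences between paralogous
hairpins. Because the mapper treats `N` as matching nothing, a read
overlapping two or more masked bases cannot hit the precursor at all, so
precursor counts consist purely of reads mapping exclusively to precursor
flank/loop sequence.

Two mature targets where the shorter is a contiguous substring of the
longer and exactly one base shorter form a *nested pair*. Reads of the
shorter sequence unavoidably map to both; counting first credits them to
the longer target flagged as shared, and a subtraction step then assigns
short = (total on long) − (unique to long), long = (unique to long). The
longer target's reported count after subtraction is its unique count: that
is the only convention that conserves the pair total, and conservation is
enforced (a negative intermediate raises). Containments with a length
difference of two or more bases are surfaced as warnings but not given the
subtraction treatment.

RNA alphabets are converted U→T at parse time; all mapping happens in DNA
space since reads are DNA. Mature→hairpin child relations are resolved by
the name-extension convention (mature name equals the hairpin name or
extends it after a `-`), with an explicit two-column TSV override for
inputs whose headers do not follow it.

## Read processing and mapping

Demultiplexing requires a perfect match to the index barcode. Adapter
clipping cuts at the leftmost position where either a full adapter
occurrence begins or an adapter prefix of at least `min_overlap` (default
3) bases runs to the read end; reads without a detectable adapter are kept
and left to the 18–30 nt length filter, which is inclusive at both bounds.
Identical reads are collapsed to unique sequences with multiplicities
(emitted as `>seq<i>_x<multiplicity>` FASTA when serialized). Quality
strings are carried but never used for filtering.

The mapping contract is: report every (target, offset) placement of the
full read with Hamming distance ≤ 1, no gaps, read fully contained in the
target. The implementation splits the read in two halves; with at most one
mismatch at least one half matches exactly, so looking up the leading
9-mer of each half in an exact k-mer index of the targets and Hamming-
verifying each candidate placement is complete, not heuristic. 9 is the
largest seed length valid for the shortest retained read (18 nt). Any
alignment column involving `N` (either side) counts as a mismatch. Reads
shorter than 2×9 nt fall back to a full scan with the identical contract.
The test suite holds the mapper to exact equivalence with a brute-force
all-targets, all-offsets scan on randomized instances.

## Counting rules

Per unique read, weighted by multiplicity: (1) if any 0-mismatch hit
exists, 1-mismatch hits are discarded; (2) precursor hits are discarded if
a mature hit remains; (3) a single remaining target receives the count;
(4) exactly the two members of a registered nested pair go to the long
target flagged shared; (5) anything else is ambiguous — kept in the
library's mapped total but assigned to no target, so per-target counts stay
auditable (the ambiguous mass is logged and reported). Reads counted via a
1-mismatch hit are tallied separately in the mismatch sub-table, always a
subset of the totals. Per library, assigned + ambiguous + unmapped must
equal the filtered read count; the pipeline refuses to continue otherwise.

CPM and percent abundance divide by the per-library sum of counted target
reads (the total reads mapped to miRNAs, not the raw read count), so CPM
columns sum to 10⁶ exactly. The highly-expressed set takes targets
strictly above 100 CPM in at least one library; strictness follows the
definition of the threshold as "over 100".

## Ratio statistics

For one condition (gonadal state × diet) and one contrast, the numerator
is the arithmetic mean of the two numerator-genotype libraries' CPM and
likewise the denominator; the per-miRNA statistic is the log2 of that
ratio over the highly-expressed set. miRNAs with a zero group mean receive
a 0.5-CPM pseudocount added to both means and are flagged; the
highly-expressed filter makes this rare, and pseudocounted ratios are kept
rather than dropped so that profile length stays interpretable.

Histograms use half-open 0.5-wide bins spanning [−4, 4], with values below
−4 in the first bin and 4 or above in the last. The sign-bias test is the
exact two-sided binomial test of positive vs. negative ratios against 0.5,
excluding exact zeros (a zero carries no directional information).
Condition comparisons use the two-sided Wilcoxon rank-sum test: exact when
both sides have ≤20 untied observations, otherwise the tie-corrected
normal approximation with continuity correction (midranks for ties). Both
tests are two-sided because direction is an output, not an assumption.

PCA treats libraries as observations and miRNAs as features, on
log2(CPM+1) with mean-centering and no unit-variance scaling — the log
keeps the handful of dominant miRNAs from owning every component, and
skipping variance scaling avoids inflating near-threshold noise; the raw
CPM transform is available as an option. Component signs follow a fixed
convention (largest-magnitude loading positive) so runs are reproducible.
Variance fractions are reported over all components and sum to one.

## Synthetic experiment generator

The generator emulates the 12-library FCG study: four genotypes (XX-F,
XX-M, XY-F, XY-M) under intact-chow, GDX-chow and GDX-HFD conditions, one
pooled library per cell, each with a distinct TruSeq index barcode.

* **Reference structure.** Random mature sequences of 18–24 nt, with a
  configurable number of gene families sharing one mature sequence and of
  nested pairs differing by one terminal base (default 7 pairs, matching
  the scale at which real references exhibit them). Each gene gets a
  hairpin of the mature plus random flanks; drawing rejects any accidental
  equality/containment among matures or mature-in-foreign-precursor
  occurrence, so the only shared sequence structure is the planted one.
* **Expression.** A log-normal baseline with sigma 2.0 shared across
  libraries reproduces the real dominance structure in which a few miRNAs
  carry about half of all reads. Planted effects are multiplicative
  (additive in log2): a sex effect applied to male libraries, a chromosome
  effect applied to XY libraries (both overridable per condition), and a
  diet effect applied with a random fixed sign per miRNA to high-fat
  libraries.
* **Which miRNAs carry effects.** Effects hit a random subset (default
  fraction 0.8) of miRNAs drawn from outside the top decile of baseline
  expression. CPM is compositional: an effect planted on the dominant
  miRNAs moves the per-library denominator by nearly the full effect size
  and cancels the very bias it should create, while sparing the dominant
  species keeps the normalization shift small. Biologically this reads as
  the super-abundant housekeeping-like miRNAs being stable while the mid-
  and low-abundance tail responds.
* **Reads.** Per-library counts are one multinomial draw at the configured
  depth (truth counts sum to depth by construction). Each read is its
  mature sequence with uniform substitution errors at the per-base error
  rate (no indels — the mapper is ungapped), followed by the full 3'
  adapter; read IDs encode library, source target and planted error count,
  so provenance is verifiable read by read. The default error rate of 0.03
  makes roughly 85–87% of 18–24 nt reads mappable at ≤1 mismatch,
  squarely inside the 80–90% range reported for real libraries; errors are
  the single stand-in for everything that keeps real reads from mapping
  (other RNA species, degradation, untrimmable adapters), which the
  generator does not model separately.
* **Pooling study.** Replicate libraries of one genotype are generated
  from log-normally jittered copies of the expression profile (sigma 0.3),
  and the pooled library from the mean of those profiles at matched depth,
  mirroring equimolar pooling of biological replicates.

The `paper-like` preset plants the study's qualitative pattern: male bias
when gonads are intact on chow (sex effect +0.5 log2 on males), a smaller
female bias after gonadectomy (−0.4), male plus XY bias under high fat
diet (+0.5 each), and a strong diet effect (±1.5 log2 on 40% of miRNAs)
that dominates library covariance. These sizes come from a power analysis:
planted sign biases must be detectable by an exact binomial test over a
~180-member highly-expressed set at the desk-scale depths used below in at
least 90% of seeds, and the GDX-HFD chromosome effect at ±0.4 sat at the
edge of that power. The generator is fully deterministic under its seed,
to the byte, including FASTA/FASTQ/qseq output.

### What passing tests do and do not show

The generator draws reads from mature sequences only, with flat qualities,
no indels, no isomiR 5'/3' heterogeneity, no estrous-cycle or cage
variance beyond the replicate jitter, and no non-miRNA contaminant reads.
Tests passing on this synthetic data demonstrate that the pipeline's
bookkeeping is exact (truth recovery at zero noise is bit-for-bit), that
the mapper meets its contract, and that the statistics recover planted
distribution-level effects at realistic depths — they do not certify
behavior on RNA whose variability lies outside this model, in particular
isomiR-rich data where length heterogeneity would interact with the
nested-pair rule.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep the whole
suite fast while leaving the statistics well-powered: zero-noise identity
at depth 10⁵ per library across all 12 libraries; the mapping-rate
closed-form check over >10⁵ reads of exactly 22 nt at 2% error (expected
rate (0.98)²² + 22·0.02·(0.98)²¹ ≈ 92.5%); bias recovery over 20 seeded
experiments of 200 genes at depth 5×10⁴ per library; the pooling
correlation at depth 10⁶. Degenerate inputs fail loudly rather than
silently: zero-count libraries, empty ratio profiles, all-zero sign tests,
constant correlation vectors, fewer than three PCA libraries, and negative
nested-subtraction intermediates all raise with specific messages, and an
empty highly-expressed set is reported as a clean stats-stage error in the
result bundle rather than a crash.

## Known limitations

* Only the ≤1-mismatch ungapped mapping mode exists; there is no gapped
  alignment, quality trimming, or novel-miRNA discovery.
* Normalization is CPM only — no between-library variance-stabilizing
  normalization — and there is deliberately no per-miRNA differential
  test: with one pooled library per genotype/condition cell the design has
  no replication at that level, so all inference is distribution-level.
* Nested-pair handling covers length-difference-1 containments only;
  longer containments warn.
* The reference builder assumes name conventions or an explicit child map
  for mature↔hairpin relations; it does not fetch or pin reference
  releases.
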