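# Methods

This note documents the models, estimators and design choices behind
`lincscreen`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical decisions a
maintainer would want to know.

## Transcript catalog

A de novo transcript is retained as a lincRNA candidate iff its genomic span
(first to last exon) overlaps no annotated gene span, on either strand. Using
full gene spans rather than exons deliberately removes intronic non-coding
RNAs, matching the "intergenic" class of de novo assembly class codes. Any
reference gene feature excludes a candidate, including transposable-element
genes. Internally all coordinates are 0-based half-open; GTF I/O converts to
the format's 1-based inclusive convention (reading via gffutils, in-memory).

Neighbor scanning reports annotated genes whose span lies within a window
(default 10,000 nt, inclusive at exactly the window size) of the lincRNA
span, with signed indices counting outward (−1 nearest upstream, +1 nearest
downstream) and distance measured as intervening bases (0 for adjacency).
Conservation means are length-weighted averages over a bedGraph track,
computed separately for exonic and intronic bases; bases absent from the
track are skipped, not scored 0.

## Expression statistics

**Normalization** is plain median-of-ratios: size factor s_j = median over
loci with all-positive counts of count_ij / (geometric mean of locus i).
There is no pseudo-reference fallback by default; a data set with no
all-positive locus raises an error suggesting one.

**Differential expression** uses a negative-binomial Wald test per contrast
(A, B): FC = (mean normalized A + 0.5)/(mean normalized B + 0.5) — the 0.5
pseudocount is configurable — and z = log FC / se with the delta-method
standard error se² = (1/n_A)(1/μ_A + α) + (1/n_B)(1/μ_B + α). The common
dispersion α is a pooled method-of-moments estimate, α =
Σ(var−mean)/Σ(mean²) across all loci and both replicate groups, floored at
1e−8. The pooling is precision-weighted (mean² weights), which makes the
estimate nearly unbiased at n = 3; a per-locus median of MoM estimates is
biased low by the skew of three-replicate variances and measurably inflates
the null (KS distance vs uniform ≈ 0.05 instead of ≈ 0.02). There is no
dispersion shrinkage, trend fitting, independent filtering or outlier
handling: the caller is intentionally plain, keeping the published
fold-change/padj interface so that the screen thresholds are faithful.
p-values are two-sided normal tails, BH-adjusted within each contrast (the
per-contrast choice mirrors the pairwise-comparison framing of the design).

"Fold change > 2" is always interpreted as two-fold in either direction
(FC > 2 or FC < 0.5, strict), which is how published tables list FC = 0.06
rows as significant. The polysome-association threshold is **inclusive**
(≥ 1.3 or ≤ 1/1.3): the rule is "at least 30% increase or decrease", and a
printed passing example sits at exactly 1.3.

**Polysome shifts**: per matched replicate, PA = log((polysomal + 0.5)/
(total + 0.5)) on normalized counts; the PA fold change is exp(mean PA_A −
mean PA_B) and the p-value a two-sample equal-variance t-test on the
replicate-level PA values, BH-adjusted. Replicates are matched across
fractions by (condition, replicate index).

**Pearson profiles** correlate untransformed condition-mean normalized
counts across the full design (12 conditions by default). Constant profiles
return NaN with a warning, never ±1, and designs with fewer than three
conditions yield NaN rather than an error in the screens (the correlation is
auxiliary there).

## Homology engine

One scoring scheme drives all four screens: match +2, mismatch −3, gap open
5, gap extend 2 (a gap of length g costs 5 + 2g — classic nucleotide-BLAST
convention), with Karlin–Altschul E = K·m·n·exp(−λS). λ solves
Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 at uniform base composition (λ ≈ 0.632 for +2/−3);
K defaults to 0.41. The search space is query length × total database
letters, with no finite-size edge correction. N never matches.

Two alignment paths share the scheme:

* **Full dynamic programming** (exact affine-gap Smith–Waterman) for
  problems up to 2×10⁶ cells, anti-diagonal vectorized with numpy in a
  skewed matrix layout; scores are integers held in float32, so traceback
  uses exact equality. The top hit is exact (verified against an
  independent C implementation of Smith–Waterman on hundreds of random
  pairs); further non-overlapping hits are enumerated greedily from the
  score matrix with early-abort tracebacks and a bounded attempt budget, so
  secondary hits are best-effort, never sharing query or subject bases with
  an earlier hit.
* **Seed-and-extend** for the scans: exact 9-mer word matches select
  candidate diagonals, and on each seeded diagonal the optimal *ungapped*
  local segment is found exactly by a maximum-subarray sweep over the whole
  diagonal. This reports no gapped alignments; the planted and biological
  near-duplexes the screens target are gap-free at the operating identity,
  and the word size of 9 keeps the probability of missing a ≥100-nt segment
  at 75% identity negligible (expected ≈8 seeds per duplex).

The screens apply **E < 1 (strict) and alignment length ≥ 100 (inclusive)**
for antisense and chromatin targets, and **E < 1e−12, ≥ 50 nt** for the TE
library. Length trimming matters at the margin: the optimal local segment of
a 120-nt region at 75% identity drops below 100 nt in ≈6% of random mutation
placements (a property shared by any maximal-scoring-segment aligner), which
sets the ceiling on duplex recovery discussed below. Chromatin windows span
[TSS − 2000, gene end] on the annotated strand, truncated at chromosome
edges; both strands of the window are searched, hits carry genomic
(forward-strand) subject coordinates and promoter/gene-body overlap flags,
and strandless genes are skipped with a warning. For library scans the best
hit per (lincRNA, element) pair is retained.

## Small-RNA profiles

Reads of 18–28 nt are placed by exact full-length string matching of the
read or its reverse complement against transcript sequences — a read maps at
every matching start position. Exact matching replaces short-read alignment
at this scale because the downstream statistic consumes only placement
counts. A read is attributed to a region by its start position (midpoint
optional). Complementary intervals from multiple targets are unioned per
transcript; density is reads per nt inside vs outside the union, and the
enrichment is their ratio (infinite when only the complementary region has
reads; undefined when neither does, or when the complementary region covers
the whole transcript — then the transcript is not callable and a warning is
raised). A precursor call requires ≥ 5 unique read *sequences* in the
complementary region and enrichment ≥ 2.

## miRNA screens

The mimic detector enumerates, for every lincRNA window and every bulge
placement, an antiparallel pairing with a 3-nt target-side bulge between
miRNA pairing positions b and b+1 for b ∈ {9, 10, 11} — i.e. the bulge lies
opposite miRNA positions 9–12, the IPS1/miR399 configuration; the
alternative 3′-counted convention sits behind a switch. Rules: positions 2–8
perfectly Watson–Crick; at most 3 mismatches or G:U pairs over the remaining
paired positions (the bulge not counted). Overlapping placements of one
physical site collapse to the placement with the fewest mismatches. The
detector is vectorized per (miRNA, bulge) over all windows and is verified
against an exhaustive rule-enumeration oracle on thousands of site mutants.

Binding sites are scored on ungapped windows with the classical plant
penalty scheme — mismatch 1, G:U 0.5, doubled within miRNA positions 2–13 —
reporting windows with expectation ≤ 3. The gap penalty (2) is kept in the
configuration for completeness but no gapped search is performed, and no
unpaired-energy (secondary-structure) filtering is attempted; reported sites
carry `upe_not_evaluated=True`.

## Synthetic data generator

The generator emulates the data layout of a 12-condition × 3-replicate
polysome-profiling study (high/low phosphate; root/shoot ×
control/IAA/ABA/MeJA/ACC) at desk scale — defaults: 2 chromosomes × 200 kb,
40 multi-exon coding genes with 2 kb reserved on both sides for promoters,
24 strictly intergenic lincRNAs (plus intronic decoy transcripts that the
catalog step must remove). Sequences are i.i.d. uniform ACGT outside planted
segments. Planted structure:

* antisense pairs: a mutated reverse-complement copy of a random mRNA
  segment (default 120 nt at identity 0.75) written into a lincRNA exon;
* chromatin pairs: a segment of the target's promoter window, in either
  orientation, likewise embedded;
* polysome-association pairs: an embedded duplex plus a polysomal-only
  count effect on the target;
* neighbor pairs: a lincRNA and its nearest gene within 10 kb (preferring
  genes not already used as targets, keeping truth keys disjoint);
* TE insertions (exact 150–300-nt fragments) into lincRNAs and two
  promoters; mimic sites as perfect-complement constructs with the 3-nt
  bulge; siRNA hotspots confined to duplex regions of designated precursor
  lincRNAs (half of the antisense pairs).

Counts are drawn directly from a negative binomial (common dispersion 0.05)
with log-uniform library size factors in [0.5, 2] — the study does not state
its library-size spread, so this range is a package decision. Each planted
pair shares a condition profile: ±½ log-effect on the designated contrast
(low vs high phosphate) and correlated N(0, 0.45) variation elsewhere,
scaled by the fold-change effect (default 4) for steady state and by the PA
effect (default 1.5) on the polysomal fraction only for PA targets; the
target's profile is sign-flipped for negative pairs. The overall sign of
each pair's profile is balanced by a greedy counter so about half the
planted lincRNAs are up- and half down-regulated — besides being what real
designs look like, an unbalanced panel measurably biases median-of-ratios
size factors on a 70-locus miniature. Small reads draw lengths from a
discrete distribution over 18–28 nt with mode 24, background uniform over
transcripts at 0.02 reads/nt, hotspot reads (default 40) confined to the
duplex region, and a quarter-strength hotspot on the target side of
precursor pairs (the weaker target-side enrichment seen in real siRNA data).

What the generator does **not** emulate: read-level sequencing noise (counts
are drawn, not assembled from reads), splicing noise and isoform ambiguity,
per-gene dispersion trends, GC or mappability biases, genome-wide small-RNA
multi-mapping, and realistic repeat structure. Passing tests therefore
demonstrate that the pipeline's logic recovers the regulatory structure it
is designed to detect under its stated noise model — not that it is robust
to assembly or alignment artifacts of real data.

Everything is driven by one integer seed; identical seed and configuration
give byte-identical output files.

## Expected recovery and metric definitions

With default effect sizes, end-to-end recovery of planted pairs (correct
direction, matching interaction type) runs ≈ 85–95% over seeds. The binding
constraint is alignment-length trimming at the duplex operating point
(above), not the expression tests, whose power at a 4-fold effect and n = 3
is ≈ 1. Spurious-call rates are evaluated over pairs with at least one
unplanted member: pairs between two planted loci share the designated
contrast by construction, so their co-expression is real and calling them is
correct screen behaviour, not a false positive. siRNA-precursor sensitivity
is measured over planted precursors recovered as trans-NATs (the scoring
contract presupposes a complementary region; antisense-scan misses are
already covered by the pair-recovery bound), and the false-positive rate
over all classified lincRNAs that are not planted precursors.

## Pipeline

Stages run in dependency order from a single configuration object
(`PipelineConfig`); every threshold has its published default and reaches
stage code only through the configuration — there are no hard-coded screen
constants in stage logic. Each output table carries a `config_hash` column
(SHA-1 of the sorted threshold manifest) and the run writes a frozen copy of
the effective configuration and a `manifest.json` next to the outputs. The
problem sizes used in tests and in `scripts/acceptance.py` (the default
miniature bundle, 10–20 simulation seeds, 2,000-locus statistical panels,
200 alignment-oracle pairs) are the package's chosen desk-scale operating
points; all complete in seconds to a few minutes on one CPU.

## Known limitations

* The NB Wald caller is anti-conservative for very low counts (μ < ~5) and
  has no outlier handling; it is a screen-grade test, not a DESeq2
  replacement.
* Greedy secondary-hit enumeration in the DP path can omit suboptimal
  alignments overlapping a better hit's shadow; only the top hit per pair is
  guaranteed optimal (and only the top hit feeds the screens).
* The seeded scan path reports ungapped segments only; indel-containing
  duplexes would be found split or not at all.
* The mimic/binding screens ignore RNA secondary structure entirely.
* E-values use ungapped Karlin–Altschul statistics with a fixed K; absolute
  E-values for gapped alignments are approximate (the screens' thresholds
  were calibrated under the same convention, so the filters are
  self-consistent).
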