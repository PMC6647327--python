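# lincscreen

Screens for **trans-acting regulatory lincRNA candidates** in a
multi-condition polysome-profiling RNA-seq design.

Long intergenic non-coding RNAs (lincRNAs) can regulate distant
protein-coding genes through nucleic-acid base pairing: as
*trans*-natural antisense transcripts (trans-NATs) that pair partially with a
target mRNA, or as RNA:DNA hybrid candidates that share homology with a
target gene's chromatin (gene body plus promoter) and may form R-loops.
`lincscreen` implements the complete screening pipeline that turns transcript
annotations, total and polysome-associated count matrices, small-RNA reads
and sequence libraries into directional lincRNA → target candidate calls —
plus a synthetic-data generator that plants recoverable regulatory structure
so the whole pipeline is testable without any external download.

It is aimed at computational biologists working on plant (or other
eukaryotic) lncRNA regulation who want a transparent, scriptable
re-implementation of this class of screen.

## The screens

With fold change FC reported condition-A-relative for a contrast (A, B), and
p-values Benjamini–Hochberg adjusted:

* **Catalog** — a de novo transcript is a lincRNA candidate iff its span
  overlaps no annotated gene on either strand (removing intronic RNAs).
* **Homology** — one local-alignment engine (match +2, mismatch −3, gap
  open 5 / extend 2; Karlin–Altschul E = K·m·n·e^(−λS)) drives four screens:
  antisense lincRNA vs reverse-complemented mRNAs and lincRNA vs chromatin
  windows `[TSS − 2000, gene end]` with **E < 1 and alignment ≥ 100 nt**;
  transposable-element content with **E < 1e−12 and ≥ 50 nt**; and
  miRNA-hairpin homology.
* **Steady state** — a hit becomes a candidate pair in a contrast when both
  members have mean normalized counts > 10, |log₂ FC| > 1 and padj < 0.1;
  direction is *positive* when both move the same way, *negative* otherwise.
* **Translation** — the lincRNA passes the DE thresholds and the target's
  polysome-association ratio (polysomal/total, the translation proxy) shifts
  by ≥ 30 % at padj < 0.1.
* **Neighbors** — the same direction rule applied to genes within 10 kb of a
  lincRNA.
* **Robustness** — each pair carries the Pearson correlation of
  condition-mean profiles across the 12-condition design; |r| > 0.6 flags
  the most robust candidates.
* **Small RNA** — a trans-NAT is an siRNA-precursor candidate when ≥ 5
  unique 18–28-nt reads map to its target-complementary region at ≥ 2× the
  density of the rest of the transcript.
* **miRNA mimics** — perfect Watson-Crick seed pairing (miRNA positions
  2–8), a 3-nt target-side bulge opposite positions 9–12, at most 3
  mismatches/G:U elsewhere.

## Worked example

The direction rule applied to the published Arabidopsis candidate tables
(`python examples/07_published_tables.py`):

```
steady-state pairs:
  trans_nat    target  tNAT_FC  trgt_FC direction
XLOC_003697 AT4G28790     2.80     2.43  positive
XLOC_000486 AT1G66320     2.27     3.88  positive
XLOC_002538 AT3G48640     0.06     0.21  positive
XLOC_001309 AT3G22370     0.33     0.28  positive
XLOC_003241 AT4G01770     2.79     4.57  positive
XLOC_003681 AT5G41380     0.06     4.73  negative
XLOC_002538 AT5G66670     0.06     3.70  negative
XLOC_001125 AT1G63350     5.12     0.44  negative
-> 5 positive, 3 negative
```

Both members of each *positive* pair move the same way (both up, or both
down, as for XLOC_001309/AT3G22370); *negative* pairs move oppositely. The
full pipeline on a synthetic bundle (`python examples/04_trans_nat_screen.py`)
prints, among others:

```
lincRNA candidates: 24
antisense hits: 6, chromatin-window hits: 8, TE hits: 3
...
XLOC_000003 AT2G00310     rna_rna  negative     -0.829    True
XLOC_000005 AT1G00160     rna_rna  positive      0.906    True
...
planted pairs recovered: 10/11
```

i.e. of 11 planted regulatory pairs, 10 are re-identified with the correct
direction, and the attached Pearson r (with the robust flag at |r| > 0.6)
tracks the planted correlation sign.

The `examples/` directory has one short script per capability (simulation,
catalog, expression tests, screens, small-RNA precursors, miRNA mimics). A
thin CLI mirrors the stages (`lincscreen simulate | run-all | catalog | de |
pa | scan-rna | scan-dna | scan-te | smallrna | mirna | screen | network |
summarize`).

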