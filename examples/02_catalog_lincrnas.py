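"""Classify de novo transcripts as intergenic lincRNAs and profile them.

A candidate is kept only if its span overlaps no annotated gene on either
strand (removing intronic RNAs); features and 10-kb neighbor indices are
computed for the retained set.
"""

from lincscreen import (
    SyntheticConfig,
    classify_intergenic,
    generate_annotation,
    neighbor_scan,
    transcript_features,
)

ann = generate_annotation(SyntheticConfig(seed=1))
lincs = classify_intergenic(ann.denovo, ann.reference, chromosomes=set(ann.genome))
print(f"{len(ann.denovo)} de novo transcripts -> {len(lincs)} intergenic lincRNA candidates")
print(f"({len(ann.denovo) - len(lincs)} removed for overlapping annotated genes)")

track = ann.conservation_track()
feats = [transcript_features(t, track) for t in lincs[:5]]
print("\nfirst candidates (length / GC / introns / exonic conservation):")
for f in feats:
    cons = f"{f.mean_conservation_exon:.2f}" if f.mean_conservation_exon else "-"
    print(f"  {f.transcript_id}: {f.length} nt, GC {f.gc_fraction:.2f}, "
          f"{f.n_introns} introns, cons {cons}")

neighbors = neighbor_scan(lincs[0], ann.reference, window=10_000)
print(f"\nneighbors of {lincs[0].id} within 10 kb "
      f"(index -1 = nearest upstream, +1 = nearest downstream):")
for nb in neighbors:
    print(f"  {nb.index:+d}: {nb.gene_id} at {nb.distance} nt")
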