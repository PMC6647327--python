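"""Simulate a miniature polysome-profiling study bundle with planted structure.

Generates two short chromosomes with coding genes and intergenic lincRNAs,
plants antisense duplexes, promoter homologies, TE insertions, mimic sites
and siRNA hotspots, and writes the bundle (FASTA/GTF/TSV) to disk.
"""

from lincscreen import SyntheticConfig, generate_annotation, pipeline

config = SyntheticConfig(seed=1)
annotation = generate_annotation(config)
bundle = pipeline.simulate_bundle(config)
outdir = pipeline.write_bundle(bundle, "example_bundle", ann=annotation)

truth = bundle.truth
print(f"bundle written to {outdir}/")
print(f"chromosomes: {len(bundle.genome)}, coding genes: {len(bundle.reference)}, "
      f"de novo transcripts: {len(bundle.denovo)}")
print(f"planted pairs: {len(truth.planted_pairs)} "
      f"({sum(p.interaction == 'rna_rna' for p in truth.planted_pairs)} antisense, "
      f"{sum(p.interaction == 'rna_dna' for p in truth.planted_pairs)} chromatin, "
      f"{sum(p.interaction == 'neighbor' for p in truth.planted_pairs)} neighbor)")
print(f"polysome-association pairs: {len(truth.planted_pa_pairs)}, "
      f"TE insertions: {len(truth.planted_te)}, mimic sites: {len(truth.planted_mimics)}, "
      f"siRNA precursors: {len(truth.planted_sirna_precursors)}")
print(f"count matrices: {bundle.total.data.shape[0]} loci x {bundle.total.data.shape[1]} samples "
      f"per fraction; small reads: {len(bundle.reads)}")
# Every downstream screen is expected to recover this planted structure;
# the truth tables written next to the bundle are the key for checking it.
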