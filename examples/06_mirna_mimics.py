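"""Detect miRNA target mimics and (cleavable) binding sites on lincRNAs.

A mimic pairs the miRNA perfectly at seed positions 2-8 but bulges out three
target-side nucleotides opposite miRNA positions 9-12 (the cleavage site), so
the miRNA is sequestered without slicing. Binding sites are scored with the
classical plant penalty scheme (mismatch 1, G:U 0.5, doubled at positions
2-13); expectation <= 3 is reported.
"""

from lincscreen import SyntheticConfig, find_binding_sites, find_mimic_sites, generate_annotation

ann = generate_annotation(SyntheticConfig(seed=1))
lincs = {r.id: r for r in ann.denovo}

print("mimic truth:", ann.truth.planted_mimics)
for linc_id, mir_id, pos in ann.truth.planted_mimics:
    calls = find_mimic_sites(lincs[linc_id].sequence, ann.mirna_library[mir_id],
                             lincrna_id=linc_id, mirna_id=mir_id)
    for c in calls:
        print(f"  {linc_id} x {mir_id}: site {c.site_start}-{c.site_end}, "
              f"bulge after miRNA position {c.bulge_after_position}, "
              f"{c.n_mismatch_plus_gu} mismatches/G:U")

# a perfect complement of the first miRNA scores expectation 0
from lincscreen.io import revcomp

mir_id = sorted(ann.mirna_library)[0]
mir = ann.mirna_library[mir_id]
synthetic_target = "ACGT" * 10 + revcomp(mir) + "TGCA" * 10
sites = find_binding_sites(synthetic_target, mir, mirna_id=mir_id)
print(f"\nbinding site for {mir_id} on a perfect-complement target: "
      f"expectation {sites[0].expectation} at {sites[0].site_start} "
      f"(0 = no penalties; threshold 3.0)")
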