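"""Synthetic bundle generator: construction guarantees and effect recovery."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

from lincscreen import (
    SizingError,
    SyntheticConfig,
    generate_annotation,
    generate_counts,
    generate_small_reads,
    local_align,
    normalize_counts,
    polysome_shift,
)
from lincscreen.io import revcomp


def _lincs(ann):
    return [r for r in ann.denovo if not r.id.startswith("XLOC_D")]


def test_empty_lincrna_config_gives_empty_truth():
    cfg = SyntheticConfig(
        n_lincRNAs=0, n_planted_rnarna_pairs=0, n_planted_dna_pairs=0,
        n_planted_neighbors=0, n_planted_pa_pairs=0, n_te_insertions=0,
        n_mimic_sites=0, seed=3,
    )
    ann = generate_annotation(cfg)
    assert _lincs(ann) == []
    assert ann.truth.planted_pairs == []
    assert ann.truth.planted_te == []


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SyntheticConfig(planted_identity=0.4)
    with pytest.raises(ValueError):
        SyntheticConfig(planted_duplex_length=80)
    with pytest.raises(ValueError):
        SyntheticConfig(n_lincRNAs=-1)


def test_infeasible_layout_raises_sizing_error():
    with pytest.raises(SizingError):
        generate_annotation(SyntheticConfig(chromosome_length=20_000, seed=1))
    with pytest.raises(SizingError):
        generate_annotation(SyntheticConfig(n_lincRNAs=2, seed=1))  # fewer than roles


def test_identity_one_duplex_aligns_without_mismatch():
    cfg = SyntheticConfig(planted_identity=1.0, planted_duplex_length=120, seed=5)
    ann = generate_annotation(cfg)
    by_id = {r.id: r for r in ann.reference + ann.denovo}
    for pair in ann.truth.planted_pairs:
        if pair.interaction != "rna_rna":
            continue
        linc = by_id[pair.lincrna_id]
        target = by_id[pair.target_id]
        hits = local_align(linc.sequence, revcomp(target.sequence), method="seed", min_score=50)
        assert hits, f"planted duplex of {pair.lincrna_id} not recovered"
        assert hits[0].aln_length >= 120
        assert hits[0].n_mismatch == 0


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    from lincscreen import pipeline

    cfg = SyntheticConfig(seed=9)
    dirs = []
    for name in ("a", "b"):
        ann = generate_annotation(cfg)
        bundle = pipeline.simulate_bundle(cfg)
        out = tmp_path / name
        pipeline.write_bundle(bundle, out, ann=ann)
        dirs.append(out)
    files = sorted(p.name for p in dirs[0].iterdir())
    assert files
    for f in files:
        assert (dirs[0] / f).read_bytes() == (dirs[1] / f).read_bytes()


def test_truth_table_ids_exist_in_annotation(annotation):
    known = {r.id for r in annotation.reference} | {r.id for r in annotation.denovo}
    truth = annotation.truth
    for p in truth.planted_pairs + truth.planted_pa_pairs:
        assert {p.lincrna_id, p.target_id} <= known
    assert {l for l, _, _ in truth.planted_mimics} <= known
    assert {l for l, _ in truth.planted_te} <= known
    assert set(truth.planted_sirna_precursors) <= known


def test_null_panel_when_fold_change_effect_is_one(annotation):
    cfg = dataclasses.replace(SyntheticConfig(seed=11), seed=77, fold_change_effect=1.0, pa_effect=1.0)
    total, _ = generate_counts(annotation, cfg)
    means = normalize_counts(total).condition_means()
    log_ratio = np.log(means.max(axis=1) / means.min(axis=1))
    # no planted structure: condition spread stays at sampling-noise scale
    assert float(np.median(log_ratio)) < 0.6


def test_planted_fold_change_recovered_across_seeds(annotation):
    """Planted 4-fold members show empirical FC in [2.5, 6.5] (>=90% of members)."""
    base = SyntheticConfig(seed=11)
    ca, cb = base.designated_contrast
    in_range = []
    for s in range(40):
        cfg = dataclasses.replace(base, seed=5000 + s)
        total, _ = generate_counts(annotation, cfg)
        means = normalize_counts(total).condition_means()
        for p in annotation.truth.planted_pairs:
            if p.interaction != "rna_rna":
                continue
            for locus in (p.lincrna_id, p.target_id):
                f = means.loc[locus, ca] / means.loc[locus, cb]
                f = max(f, 1.0 / f)
                in_range.append(2.5 <= f <= 6.5)
    assert np.mean(in_range) >= 0.9


def test_pa_effect_shifts_ratio_but_not_total(annotation):
    base = SyntheticConfig(seed=11)
    ca, cb = base.designated_contrast
    pa_fcs, total_fcs = [], []
    for s in range(40):
        cfg = dataclasses.replace(base, seed=6000 + s)
        total, polysomal = generate_counts(annotation, cfg)
        nt = normalize_counts(total)
        pa = polysome_shift(nt, normalize_counts(polysomal), (ca, cb))
        means = nt.condition_means()
        for p in annotation.truth.planted_pa_pairs:
            x = pa.loc[p.target_id, "pa_fc"]
            pa_fcs.append(max(x, 1.0 / x))
            total_fcs.append(means.loc[p.target_id, ca] / means.loc[p.target_id, cb])
    assert 1.25 <= np.median(pa_fcs) <= 1.8
    assert 0.8 <= np.median(total_fcs) <= 1.25


def test_small_read_lengths_mode_is_24(annotation):
    cfg = dataclasses.replace(SyntheticConfig(seed=11), seed=13, background_read_density=0.2)
    reads = generate_small_reads(annotation, cfg)
    lengths = Counter(len(seq) for _, seq in reads)
    assert sum(lengths.values()) >= 10_000
    assert set(lengths) <= set(range(18, 29))
    assert lengths.most_common(1)[0][0] == 24


def test_hotspot_reads_confined_to_duplex_region(annotation, syn_config):
    reads = generate_small_reads(annotation, syn_config)
    by_id = {r.id: r for r in annotation.denovo}
    truth = annotation.truth
    for linc_id in truth.planted_sirna_precursors:
        a, b = truth.duplex_intervals[linc_id]
        seq = by_id[linc_id].sequence
        inside = 0
        for _, r in reads:
            for probe in (r, revcomp(r)):
                pos = seq.find(probe)
                if pos != -1 and a <= pos < b:
                    inside += 1
                    break
        assert inside >= syn_config.sirna_hotspot_reads  # hotspot plus background
    # >= 5 unique hotspot sequences guaranteed
    assert syn_config.sirna_hotspot_reads >= 5


def test_zero_hotspot_reads_yield_no_precursors():
    cfg = SyntheticConfig(seed=21, sirna_hotspot_reads=0)
    ann = generate_annotation(cfg)
    reads = generate_small_reads(ann, cfg)
    from lincscreen import map_small_reads, score_profile

    by_id = {r.id: r for r in ann.denovo}
    for linc_id in ann.truth.planted_sirna_precursors:
        prof = map_small_reads(reads, [by_id[linc_id]])[linc_id]
        _, call = score_profile(prof, [ann.truth.duplex_intervals[linc_id]])
        assert not call.is_precursor
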