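"""Intergenic classification, features, neighbors and catalog comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincscreen import (
    ConservationTrack,
    TranscriptRecord,
    catalog_overlap,
    classify_intergenic,
    neighbor_scan,
    transcript_features,
)
from lincscreen.catalog import read_gtf, write_gtf


def _t(tid, exons, strand="+", chrom="chr1", seq=None, biotype="coding"):
    return TranscriptRecord(id=tid, chromosome=chrom, strand=strand, exons=exons,
                            sequence=seq, biotype=biotype)


class TestClassifyIntergenic:
    def test_candidate_in_reference_intron_is_excluded(self):
        gene = _t("G1", [(1000, 1400), (2600, 3000)])
        intronic = _t("C1", [(1500, 1900)])
        assert classify_intergenic([intronic], [gene]) == []

    def test_distant_candidate_is_retained_with_new_biotype(self):
        gene = _t("G1", [(1000, 2000)])
        far = _t("C1", [(7000, 7600)])
        kept = classify_intergenic([far], [gene])
        assert [r.id for r in kept] == ["C1"]
        assert kept[0].biotype == "lincRNA_candidate"

    def test_any_strand_overlap_excludes(self):
        gene = _t("G1", [(1000, 2000)], strand="+")
        anti = _t("C1", [(1500, 2500)], strand="-")
        assert classify_intergenic([anti], [gene]) == []

    def test_unknown_chromosome_raises_naming_transcript(self):
        gene = _t("G1", [(1000, 2000)])
        alien = _t("C9", [(100, 300)], chrom="chrX")
        with pytest.raises(KeyError, match="C9"):
            classify_intergenic([alien], [gene], chromosomes={"chr1"})

    def test_monotone_adding_reference_never_adds_candidates(self, rng):
        genes = [_t(f"G{i}", [(int(a), int(a) + 500)]) for i, a in
                 enumerate(rng.integers(0, 50_000, 12))]
        cands = [_t(f"C{i}", [(int(a), int(a) + 300)]) for i, a in
                 enumerate(rng.integers(0, 50_000, 30))]
        kept_small = {r.id for r in classify_intergenic(cands, genes[:4])}
        kept_big = {r.id for r in classify_intergenic(cands, genes)}
        assert kept_big <= kept_small

    def test_synthetic_bundle_retains_exactly_the_planted_lincrnas(self, annotation):
        kept = classify_intergenic(annotation.denovo, annotation.reference)
        expected = {r.id for r in annotation.denovo if not r.id.startswith("XLOC_D")}
        assert {r.id for r in kept} == expected


class TestTranscriptFeatures:
    def test_gc_and_length_arithmetic(self):
        t = _t("T1", [(0, 100)], seq="ATGC" * 25)
        f = transcript_features(t)
        assert f.length == 100
        assert f.gc_fraction == pytest.approx(0.5)
        assert f.n_introns == 0
        assert f.mean_conservation_exon is None
        assert f.mean_conservation_intron is None

    def test_constant_track_gives_that_mean_for_exons_and_introns(self):
        t = _t("T1", [(100, 200), (300, 400)], seq="A" * 200)
        track = ConservationTrack(
            {"chr1": (np.array([0]), np.array([1000]), np.array([0.8]))}
        )
        f = transcript_features(t, track)
        assert f.mean_conservation_exon == pytest.approx(0.8)
        assert f.mean_conservation_intron == pytest.approx(0.8)
        assert f.n_introns == 1

    def test_uncovered_bases_are_skipped_not_zero(self):
        t = _t("T1", [(0, 100)], seq="A" * 100)
        track = ConservationTrack(
            {"chr1": (np.array([0]), np.array([50]), np.array([0.6]))}
        )
        assert transcript_features(t, track).mean_conservation_exon == pytest.approx(0.6)

    def test_track_chromosome_mismatch_raises(self):
        t = _t("T1", [(0, 100)], seq="A" * 100, chrom="chr9")
        track = ConservationTrack({"chr1": (np.array([0]), np.array([10]), np.array([1.0]))})
        with pytest.raises(KeyError):
            transcript_features(t, track)


class TestNeighborScan:
    def test_adjacent_gene_gets_index_one_distance_zero(self):
        linc = _t("L1", [(5000, 6000)])
        gene = _t("G1", [(6000, 7000)])
        (rec,) = neighbor_scan(linc, [gene])
        assert rec.index == 1
        assert rec.distance == 0

    def test_indices_count_outward_on_both_sides(self):
        linc = _t("L1", [(50_000, 51_000)])
        genes = [
            _t("U3", [(39_500, 40_500)]), _t("U2", [(42_000, 43_000)]),
            _t("U1", [(46_000, 47_000)]), _t("D1", [(53_000, 54_000)]),
            _t("D2", [(58_000, 59_000)]),
        ]
        recs = neighbor_scan(linc, genes)
        assert {(r.gene_id, r.index) for r in recs} == {
            ("U1", -1), ("U2", -2), ("U3", -3), ("D1", 1), ("D2", 2)
        }
        # indices are a bijection onto distance ranks per side
        up = sorted((r.distance, r.index) for r in recs if r.index < 0)
        assert [i for _, i in up] == [-1, -2, -3]

    def test_window_boundary_is_inclusive_at_exactly_10000(self):
        linc = _t("L1", [(50_000, 51_000)])
        at_edge = _t("E", [(61_000, 62_000)])  # 10,000 intervening bases
        beyond = _t("B", [(61_001, 62_001)])  # 10,001
        recs = neighbor_scan(linc, [at_edge, beyond])
        assert [r.gene_id for r in recs] == ["E"]


class TestCatalogOverlap:
    def test_identical_sets_fully_shared(self):
        a = [_t("A1", [(0, 100)]), _t("A2", [(500, 700)])]
        counts = catalog_overlap(a, a)
        assert (counts.a_only, counts.b_only, counts.shared) == (0, 0, 2)

    def test_same_intervals_opposite_strand_do_not_share_when_stranded(self):
        a = [_t("A1", [(0, 100)], strand="+")]
        b = [_t("B1", [(0, 100)], strand="-")]
        assert catalog_overlap(a, b, same_strand=True).shared == 0
        assert catalog_overlap(a, b, same_strand=False).shared == 1

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)

        def rand_set(tag, n):
            out = []
            for i in range(n):
                start = int(rng.integers(0, 3000))
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(_t(f"{tag}{i}", [(start, start + int(rng.integers(50, 400)))], strand=strand))
            return out

        a, b = rand_set("A", 8), rand_set("B", 6)
        for same_strand in (False, True):
            got = catalog_overlap(a, b, same_strand=same_strand)

            def overlaps(x, y):
                if same_strand and x.strand != y.strand:
                    return False
                return any(
                    max(xa, ya) < min(xb, yb)
                    for xa, xb in x.exons
                    for ya, yb in y.exons
                )

            shared_a = sum(any(overlaps(x, y) for y in b) for x in a)
            shared_b = sum(any(overlaps(y, x) for x in a) for y in b)
            assert got.shared == shared_a
            assert got.a_only == len(a) - shared_a
            assert got.b_only == len(b) - shared_b


def test_gtf_round_trip_preserves_coordinates_and_sequence(tmp_path, annotation):
    path = tmp_path / "ref.gtf"
    write_gtf(annotation.reference, path)
    back = read_gtf(path, genome=annotation.genome)
    assert len(back) == len(annotation.reference)
    orig = {r.id: r for r in annotation.reference}
    for rec in back:
        assert rec.exons == orig[rec.id].exons
        assert rec.strand == orig[rec.id].strand
        assert rec.sequence == orig[rec.id].sequence
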