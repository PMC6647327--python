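"""Local-alignment engine, E-values and the four homology screens."""

import math

import numpy as np
import pytest

from lincscreen import (
    ScoringScheme,
    TranscriptRecord,
    local_align,
    scan_dna_targets,
    scan_library,
    scan_trans_nat,
)
from lincscreen.io import revcomp
from tests.conftest import random_dna


def _t(tid, seq, chrom="chr1", strand="+", start=0):
    return TranscriptRecord(id=tid, chromosome=chrom, strand=strand,
                            exons=[(start, start + len(seq))], sequence=seq)


class TestScoringScheme:
    def test_lambda_solves_karlin_altschul_identity(self):
        s = ScoringScheme()
        assert 0.25 * math.exp(s.lam * s.match) + 0.75 * math.exp(s.lam * s.mismatch) == pytest.approx(1.0)
        assert s.lam == pytest.approx(0.625, abs=0.02)

    def test_evalue_decreasesing_in_score(self):
        s = ScoringScheme()
        evals = [s.evalue(score, 1000, 1_000_000) for score in (20, 40, 80)]
        assert evals[0] > evals[1] > evals[2]

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1, mismatch=-3)


class TestLocalAlign:
    def test_identical_sequences_full_length_hit(self, rng):
        seq = random_dna(rng, 100)
        (hit,) = local_align(seq, seq, method="dp", max_hits=1)
        assert hit.aln_length == 100
        assert hit.n_mismatch == 0
        assert hit.percent_identity == 100.0
        assert hit.score == 200

    def test_empty_sequence_gives_no_hits(self):
        assert local_align("", "ACGT") == []
        assert local_align("ACGT", "") == []

    def test_score_symmetry(self, rng):
        for _ in range(5):
            a, b = random_dna(rng, 150), random_dna(rng, 200)
            ha = local_align(a, b, method="dp", min_score=1, max_hits=1)
            hb = local_align(b, a, method="dp", min_score=1, max_hits=1)
            assert ha[0].score == hb[0].score

    def test_n_never_matches(self):
        hits = local_align("ACGTNNNNACGT", "ACGTNNNNACGT", method="dp", min_score=5)
        assert all(h.score <= 16 for h in hits)  # the N run cannot contribute matches

    def test_seed_path_agrees_with_dp_on_ungapped_planted_segment(self, rng):
        core = random_dna(rng, 150)
        a = random_dna(rng, 60) + core + random_dna(rng, 60)
        b = random_dna(rng, 40) + core + random_dna(rng, 40)
        dp = local_align(a, b, method="dp", min_score=50, max_hits=1)[0]
        seed = local_align(a, b, method="seed", min_score=50, max_hits=1)[0]
        assert seed.score == dp.score
        assert seed.query_interval == dp.query_interval

    def test_random_pairs_never_pass_screen_filter(self, rng):
        """No random 200-mer pair yields an E<1 alignment of length >= 100."""
        for _ in range(20):
            a = random_dna(rng, 200)
            hits = local_align(a, a[::-1], method="dp", min_score=10,
                               search_space=(200, 200))
            assert not [h for h in hits if h.evalue < 1.0 and h.aln_length >= 100]


class TestScanTransNat:
    def test_embedded_reverse_complement_found_as_antisense(self, rng):
        mrna = _t("M1", random_dna(rng, 800))
        segment = mrna.sequence[300:420]
        linc = _t("L1", random_dna(rng, 200) + revcomp(segment) + random_dna(rng, 200))
        hits = scan_trans_nat([linc], [mrna])
        assert hits and hits[0].orientation == "antisense"
        assert hits[0].aln_length >= 120
        assert hits[0].percent_identity == 100.0
        # subject interval mapped back to mRNA coordinates
        sa, sb = hits[0].subject_interval
        assert (sa, sb) == (300, 420)

    def test_sense_insertion_gives_no_antisense_hit(self, rng):
        mrna = _t("M1", random_dna(rng, 800))
        segment = mrna.sequence[300:420]
        linc = _t("L1", random_dna(rng, 200) + segment + random_dna(rng, 200))
        assert scan_trans_nat([linc], [mrna]) == []

    def test_planted_pairs_recovered_on_synthetic_bundle(self, annotation):
        lincs = [r for r in annotation.denovo if not r.id.startswith("XLOC_D")]
        hits = scan_trans_nat(lincs, annotation.reference)
        found = {(h.query_id, h.subject_id) for h in hits}
        planted = {
            (p.lincrna_id, p.target_id)
            for p in annotation.truth.planted_pairs
            if p.interaction == "rna_rna"
        }
        assert len(found & planted) >= 0.75 * len(planted)


class TestScanDnaTargets:
    def test_window_arithmetic_for_both_strands_and_edges(self, rng):
        chrom = random_dna(rng, 30_000)
        genome = {"chr1": chrom}
        gplus = TranscriptRecord(id="GP", chromosome="chr1", strand="+", exons=[(10_000, 12_000)])
        gminus = TranscriptRecord(id="GM", chromosome="chr1", strand="-", exons=[(10_000, 12_000)])
        gedge = TranscriptRecord(id="GE", chromosome="chr1", strand="+", exons=[(500, 1500)])
        # lincRNA carrying copies from each expected window
        probe_plus = chrom[8_100:8_300]        # in GP promoter (8,000-10,000) only
        probe_minus = chrom[13_500:13_700]     # in GM promoter (12,000-14,000) only
        probe_edge = chrom[100:300]            # in GE promoter truncated at 0
        linc = _t("L1", probe_plus + random_dna(rng, 50) + probe_minus
                  + random_dna(rng, 50) + probe_edge)
        hits = scan_dna_targets([linc], [gplus, gminus, gedge], genome)
        by_gene = {}
        for h in hits:
            by_gene.setdefault(h.subject_id, []).append(h)

        def covers(hit, a, b):
            # chance single-base matches may extend the segment slightly
            sa, sb = hit.subject_interval
            return sa <= a and sb >= b and (a - sa) <= 5 and (sb - b) <= 5

        assert covers(by_gene["GP"][0], 8_100, 8_300)
        assert by_gene["GP"][0].in_promoter and not by_gene["GP"][0].in_gene_body
        assert covers(by_gene["GM"][0], 13_500, 13_700)
        assert by_gene["GM"][0].in_promoter
        assert covers(by_gene["GE"][0], 100, 300)

    def test_strandless_gene_skipped_with_warning(self, rng):
        genome = {"chr1": random_dna(rng, 5000)}
        g = TranscriptRecord(id="G0", chromosome="chr1", strand=".", exons=[(1000, 2000)])
        linc = _t("L1", random_dna(rng, 300))
        with pytest.warns(UserWarning, match="no strand"):
            assert scan_dna_targets([linc], [g], genome) == []

    def test_shared_te_hits_multiple_promoters(self, rng):
        te = random_dna(rng, 250)
        parts, genes = [], []
        pos = 5000
        for k in range(3):
            parts.append((pos - 2000, te))
            genes.append(TranscriptRecord(id=f"G{k}", chromosome="chr1", strand="+",
                                          exons=[(pos, pos + 1000)]))
            pos += 8000
        chrom = list(random_dna(rng, 40_000))
        for start, seq in parts:
            chrom[start : start + len(seq)] = list(seq)
        genome = {"chr1": "".join(chrom)}
        linc = _t("L1", random_dna(rng, 100) + te + random_dna(rng, 100))
        hits = scan_dna_targets([linc], genes, genome)
        assert {h.subject_id for h in hits} == {"G0", "G1", "G2"}


class TestScanLibrary:
    def test_exact_te_insertion_found_far_below_cutoff(self, rng):
        te = random_dna(rng, 200)
        linc = _t("L1", random_dna(rng, 300) + te + random_dna(rng, 300))
        hits = scan_library([linc], {"TE1": te}, max_e=1e-12, min_len=50)
        assert len(hits) == 1
        assert hits[0].evalue < 1e-12
        assert hits[0].aln_length >= 200

    def test_short_te_fragment_rejected_by_length_filter(self, rng):
        te = random_dna(rng, 300)
        linc = _t("L1", random_dna(rng, 300) + te[:40] + random_dna(rng, 300))
        assert scan_library([linc], {"TE1": te}, max_e=1e-12, min_len=50) == []

    def test_reverse_complement_insertion_found_when_both_strands(self, rng):
        te = random_dna(rng, 200)
        linc = _t("L1", random_dna(rng, 200) + revcomp(te) + random_dna(rng, 200))
        hits = scan_library([linc], {"TE1": te}, max_e=1e-12, min_len=50)
        assert hits and hits[0].orientation == "antisense"

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            scan_library([_t("L1", random_dna(rng, 100))], {})

    def test_planted_te_set_recovered_exactly(self, annotation):
        lincs = [r for r in annotation.denovo if not r.id.startswith("XLOC_D")]
        hits = scan_library(lincs, annotation.te_library, max_e=1e-12, min_len=50)
        assert {(h.query_id, h.subject_id) for h in hits} == set(map(tuple, annotation.truth.planted_te))
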