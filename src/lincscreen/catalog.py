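"""Transcript catalog: intergenic classification, features, neighbors, overlaps.

The classification step mirrors the standard de novo lincRNA workflow: a
candidate transcript assembled from RNA-seq is kept as a lincRNA candidate only
if its genomic span overlaps no annotated gene on either strand, which also
removes intronic non-coding RNAs. Neighbor scanning indexes annotated genes
within a fixed window around each lincRNA (-1 is the nearest upstream gene,
+1 the nearest downstream one), the convention used when relating lincRNAs to
flanking loci.

Coordinates are 0-based half-open internally; GTF I/O converts to the format's
1-based inclusive convention.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .io import revcomp


@dataclass
class TranscriptRecord:
    """One transcript model: coordinates, exons, strand, optional sequence."""

    id: str
    chromosome: str
    strand: str  # '+', '-' or '.'
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    sequence: str | None = None
    biotype: str = "coding"  # coding | lincRNA_candidate | reference_noncoding

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.id}: empty or inverted exon ({a}, {b})")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.sequence is not None and len(self.sequence) != self.exonic_length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != exonic length {self.exonic_length}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])]

    def splice(self, genome: dict[str, str]) -> str:
        """Extract the transcript sequence from a genome, honouring strand."""
        chrom = genome[self.chromosome]
        seq = "".join(chrom[a:b] for a, b in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def with_sequence(self, genome: dict[str, str]) -> "TranscriptRecord":
        return dataclasses.replace(self, sequence=self.splice(genome))


@dataclass
class TranscriptFeatures:
    """Per-transcript summary features (length, GC, introns, conservation)."""

    transcript_id: str
    length: int
    gc_fraction: float
    n_introns: int
    mean_conservation_exon: float | None = None
    mean_conservation_intron: float | None = None


@dataclass
class NeighborRecord:
    """An annotated gene within the neighbor window of a lincRNA.

    ``index`` counts genes outward from the lincRNA: -1, -2, ... upstream
    (lower coordinates), 1, 2, ... downstream. ``distance`` is the number of
    intervening bases between the two spans (0 for adjacency or overlap).
    """

    lincrna_id: str
    gene_id: str
    index: int
    distance: int


class ConservationTrack:
    """Per-base conservation scores held as sorted interval arrays per chromosome.

    Bases absent from the track are skipped (not scored as 0).
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.intervals = intervals

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "ConservationTrack":
        from .io import read_bedgraph

        return cls(read_bedgraph(path))

    def mean_over(self, chromosome: str, regions: list[tuple[int, int]]) -> float | None:
        """Length-weighted mean score over ``regions``; None if nothing covered."""
        if chromosome not in self.intervals:
            raise KeyError(f"chromosome {chromosome!r} absent from conservation track")
        starts, ends, scores = self.intervals[chromosome]
        total_len = 0
        total_score = 0.0
        for a, b in regions:
            i0 = int(np.searchsorted(ends, a, side="right"))
            i1 = int(np.searchsorted(starts, b, side="left"))
            if i1 <= i0:
                continue
            ov = np.minimum(ends[i0:i1], b) - np.maximum(starts[i0:i1], a)
            ov = np.clip(ov, 0, None)
            total_len += int(ov.sum())
            total_score += float((ov * scores[i0:i1]).sum())
        if total_len == 0:
            return None
        return total_score / total_len


# ---------------------------------------------------------------------------
# GTF I/O


def write_gtf(records: list[TranscriptRecord], path: str | os.PathLike, source: str = "lincscreen") -> None:
    """Write transcripts as GTF (1-based inclusive) with gene_id == transcript_id."""
    with open(path, "w") as fh:
        for rec in records:
            attrs = (
                f'gene_id "{rec.id}"; transcript_id "{rec.id}"; '
                f'transcript_biotype "{rec.biotype}";'
            )
            fh.write(
                f"{rec.chromosome}\t{source}\ttranscript\t{rec.start + 1}\t{rec.end}\t.\t{rec.strand}\t.\t{attrs}\n"
            )
            for a, b in rec.exons:
                fh.write(
                    f"{rec.chromosome}\t{source}\texon\t{a + 1}\t{b}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


def read_gtf(
    path: str | os.PathLike,
    genome: dict[str, str] | None = None,
    id_attribute: str = "transcript_id",
    default_biotype: str = "coding",
) -> list[TranscriptRecord]:
    """Read transcript models from GTF/GFF via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes[id_attribute][0]
        info = grouped.setdefault(
            tid,
            {
                "chromosome": exon.seqid,
                "strand": exon.strand or ".",
                "exons": [],
                "biotype": exon.attributes.get("transcript_biotype", [default_biotype])[0],
            },
        )
        info["exons"].append((exon.start - 1, exon.end))  # to 0-based half-open
    records = [
        TranscriptRecord(
            id=tid,
            chromosome=info["chromosome"],
            strand=info["strand"],
            exons=info["exons"],
            biotype=info["biotype"],
        )
        for tid, info in grouped.items()
    ]
    records.sort(key=lambda r: (r.chromosome, r.start, r.id))
    if genome is not None:
        records = [r.with_sequence(genome) for r in records]
    return records


# ---------------------------------------------------------------------------
# Operations


def classify_intergenic(
    candidates: list[TranscriptRecord],
    reference: list[TranscriptRecord],
    chromosomes: set[str] | None = None,
) -> list[TranscriptRecord]:
    """Retain candidates whose span overlaps no reference gene span.

    Overlap is evaluated on full gene spans (first to last exon), on either
    strand: a candidate inside a reference intron is therefore excluded, which
    removes intronic non-coding RNAs. Retained transcripts get biotype
    ``lincRNA_candidate``.
    """
    known = chromosomes if chromosomes is not None else None
    trees: dict[str, IntervalTree] = {}
    for rec in reference:
        trees.setdefault(rec.chromosome, IntervalTree()).addi(rec.start, rec.end, rec.id)
    retained = []
    for cand in candidates:
        if known is not None and cand.chromosome not in known:
            raise KeyError(
                f"transcript {cand.id}: unknown chromosome {cand.chromosome!r}"
            )
        tree = trees.get(cand.chromosome)
        if tree is not None and tree.overlap(cand.start, cand.end):
            continue
        retained.append(dataclasses.replace(cand, biotype="lincRNA_candidate"))
    return retained


def transcript_features(
    t: TranscriptRecord, conservation: ConservationTrack | None = None
) -> TranscriptFeatures:
    """Length, GC fraction, intron count and (optional) mean conservation.

    Conservation means are computed separately over exonic and intronic bases
    from the supplied track; both are None when no track is given, and the
    intronic mean is None for single-exon transcripts.
    """
    if t.sequence is None:
        raise ValueError(f"{t.id}: sequence required for feature computation")
    seq = t.sequence.upper()
    gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
    cons_ex = cons_in = None
    if conservation is not None:
        cons_ex = conservation.mean_over(t.chromosome, t.exons)
        if t.introns:
            cons_in = conservation.mean_over(t.chromosome, t.introns)
    return TranscriptFeatures(
        transcript_id=t.id,
        length=len(seq),
        gc_fraction=gc,
        n_introns=len(t.exons) - 1,
        mean_conservation_exon=cons_ex,
        mean_conservation_intron=cons_in,
    )


def neighbor_scan(
    l: TranscriptRecord,
    reference: list[TranscriptRecord],
    window: int = 10_000,
) -> list[NeighborRecord]:
    """Genes whose span lies within ``window`` nt of the lincRNA span.

    The window is inclusive: a gene exactly ``window`` intervening bases away
    is reported; one base further is not. Indices are assigned by genomic
    order outward from the lincRNA (-1 nearest upstream, +1 nearest
    downstream).
    """
    upstream: list[tuple[int, str]] = []
    downstream: list[tuple[int, str]] = []
    for gene in reference:
        if gene.chromosome != l.chromosome or gene.id == l.id:
            continue
        if gene.end <= l.start:
            dist = l.start - gene.end
            side = upstream
        elif gene.start >= l.end:
            dist = gene.start - l.end
            side = downstream
        else:  # overlap (possible only for non-intergenic queries)
            dist = 0
            side = upstream if gene.start < l.start else downstream
        if dist <= window:
            side.append((dist, gene.id))
    out: list[NeighborRecord] = []
    for rank, (dist, gid) in enumerate(sorted(upstream), start=1):
        out.append(NeighborRecord(l.id, gid, -rank, dist))
    for rank, (dist, gid) in enumerate(sorted(downstream), start=1):
        out.append(NeighborRecord(l.id, gid, rank, dist))
    out.sort(key=lambda r: r.index)
    return out


@dataclass
class OverlapCounts:
    """Venn-style catalog comparison.

    ``shared`` counts transcripts of A with at least 1 nt of exonic overlap
    with some transcript of B; ``b_only`` counts B transcripts with no exonic
    overlap with A (the two shared counts can differ when overlaps are not
    one-to-one; A's count is reported as the intersection).
    """

    a_only: int
    b_only: int
    shared: int


def catalog_overlap(
    a: list[TranscriptRecord], b: list[TranscriptRecord], same_strand: bool = False
) -> OverlapCounts:
    """Count exonic-overlap sharing between two transcript catalogs."""

    def _trees(records: list[TranscriptRecord]) -> dict:
        trees: dict = {}
        for rec in records:
            key = (rec.chromosome, rec.strand) if same_strand else rec.chromosome
            tree = trees.setdefault(key, IntervalTree())
            for x, y in rec.exons:
                tree.addi(x, y, rec.id)
        return trees

    def _shared(records: list[TranscriptRecord], trees: dict) -> int:
        n = 0
        for rec in records:
            key = (rec.chromosome, rec.strand) if same_strand else rec.chromosome
            tree = trees.get(key)
            if tree is None:
                continue
            if any(tree.overlap(x, y) for x, y in rec.exons):
                n += 1
        return n

    shared_a = _shared(a, _trees(b))
    shared_b = _shared(b, _trees(a))
    return OverlapCounts(a_only=len(a) - shared_a, b_only=len(b) - shared_b, shared=shared_a)
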