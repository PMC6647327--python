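"""Synthetic study bundle: a genome-scale design in miniature.

The generator emulates the data layout of a 12-condition x 3-replicate
polysome-profiling RNA-seq study in a plant seedling system (high/low
phosphate; root/shoot x control/IAA/ABA/MeJA/ACC), at desk scale: a couple of
short chromosomes carrying multi-exon coding genes (with 2 kb reserved
upstream for promoters) and strictly intergenic lincRNAs, plus planted
regulatory structure that every downstream screen is expected to recover:

* lincRNA:mRNA antisense duplexes (a mutated reverse-complement copy of an
  mRNA segment embedded in a lincRNA), with correlated or anti-correlated
  expression across conditions,
* lincRNA segments homologous to target promoters/gene bodies (RNA:DNA
  candidates), again with correlated expression,
* polysome-association pairs: the lincRNA shifts at steady state while the
  target shifts only in the polysomal fraction,
* correlated lincRNA-neighbor pairs within the 10 kb window,
* transposable-element insertions in lincRNAs (and a couple of promoters),
* miRNA target-mimic sites (near-complement with a 3-nt bulge opposite miRNA
  positions 9-12),
* siRNA read hotspots confined to duplex regions of designated precursor
  lincRNAs, read lengths 18-28 nt with a mode at 24.

Counts are drawn directly from a negative binomial with a common dispersion
and log-uniform library size factors; no read-level simulation is attempted.
Identical seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .catalog import ConservationTrack, TranscriptRecord
from .expression import CountMatrix, make_count_matrix
from .io import revcomp

CONDITIONS_12 = [
    "high_Pi", "low_Pi",
    "root_ctrl", "root_IAA", "root_ABA", "root_MeJA", "root_ACC",
    "shoot_ctrl", "shoot_IAA", "shoot_ABA", "shoot_MeJA", "shoot_ACC",
]

#: the pairwise comparisons screened by default (treatment vs matched control)
CONTRASTS_12 = [
    ("low_Pi", "high_Pi"),
    ("root_IAA", "root_ctrl"),
    ("root_ABA", "root_ctrl"),
    ("root_MeJA", "root_ctrl"),
    ("root_ACC", "root_ctrl"),
    ("shoot_IAA", "shoot_ctrl"),
    ("shoot_ABA", "shoot_ctrl"),
    ("shoot_MeJA", "shoot_ctrl"),
    ("shoot_ACC", "shoot_ctrl"),
    ("root_ctrl", "shoot_ctrl"),
]

TE_FAMILIES = ["RC_Helitron", "MuDR", "LTR_Copia", "LTR_Gypsy", "SINE", "LINE_L1"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SizingError(ValueError):
    """Requested features do not fit in the configured chromosomes."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic bundle; defaults are the study conditions."""

    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    n_coding_genes: int = 40
    n_lincRNAs: int = 24
    n_planted_rnarna_pairs: int = 4
    n_planted_dna_pairs: int = 4
    n_planted_neighbors: int = 3
    n_planted_pa_pairs: int = 3
    planted_identity: float = 0.75
    planted_duplex_length: int = 120
    n_conditions: int = 12
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    fold_change_effect: float = 4.0
    pa_effect: float = 1.5
    n_te_insertions: int = 3
    n_mimic_sites: int = 2
    sirna_hotspot_reads: int = 40
    background_read_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chromosome_length", "n_coding_genes", "n_lincRNAs",
            "n_planted_rnarna_pairs", "n_planted_dna_pairs", "n_planted_neighbors",
            "n_planted_pa_pairs", "n_conditions", "n_replicates", "n_te_insertions",
            "n_mimic_sites", "sirna_hotspot_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.5 < self.planted_identity <= 1.0):
            raise ValueError("planted_identity must lie in (0.5, 1.0]")
        if self.planted_duplex_length < 100:
            raise ValueError("planted_duplex_length must be >= 100")
        if self.nb_dispersion <= 0 or self.fold_change_effect <= 0 or self.pa_effect <= 0:
            raise ValueError("dispersion and effect sizes must be positive")

    @property
    def conditions(self) -> list[str]:
        if self.n_conditions == 12:
            return list(CONDITIONS_12)
        return [f"cond{i + 1:02d}" for i in range(self.n_conditions)]

    @property
    def designated_contrast(self) -> tuple[str, str]:
        """The contrast carrying the planted fold-change effect."""
        conds = self.conditions
        return (conds[1], conds[0])

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        if self.n_conditions == 12:
            return list(CONTRASTS_12)
        conds = self.conditions
        return [(conds[i], conds[0]) for i in range(1, len(conds))]


@dataclass
class PlantedPair:
    lincrna_id: str
    target_id: str
    interaction: str  # rna_rna | rna_dna | neighbor
    direction: str  # positive | negative


@dataclass
class TruthTable:
    """Ground truth of everything planted into the bundle."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_pa_pairs: list[PlantedPair] = field(default_factory=list)
    planted_mimics: list[tuple[str, str, int]] = field(default_factory=list)
    planted_te: list[tuple[str, str]] = field(default_factory=list)
    planted_sirna_precursors: list[str] = field(default_factory=list)
    duplex_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    target_duplex_intervals: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def all_pair_keys(self) -> set[tuple[str, str]]:
        keys = {(p.lincrna_id, p.target_id) for p in self.planted_pairs}
        keys |= {(p.lincrna_id, p.target_id) for p in self.planted_pa_pairs}
        return keys


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    reference: list[TranscriptRecord]
    denovo: list[TranscriptRecord]
    te_library: dict[str, str]
    mirna_library: dict[str, str]
    hairpin_library: dict[str, str]
    truth: TruthTable
    conservation_intervals: list[tuple[str, int, int, float]] = field(default_factory=list)

    @property
    def lincrnas(self) -> list[TranscriptRecord]:
        truth_ids = {r.id for r in self.denovo if not r.id.startswith("XLOC_D")}
        return [r for r in self.denovo if r.id in truth_ids]

    def conservation_track(self) -> ConservationTrack:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, a, b, s in self.conservation_intervals:
            by_chrom.setdefault(chrom, []).append((a, b, s))
        arrays = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arrays[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows], dtype=float),
            )
        return ConservationTrack(arrays)


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute a (1 - identity) fraction of positions with different bases."""
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    arr = bytearray(seq.encode())
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in sorted(positions):
        current = chr(arr[pos])
        alternatives = [b for b in "ACGT" if b != current]
        arr[pos] = ord(alternatives[int(rng.integers(0, 3))])
    return arr.decode()


def _embed(genome: dict[str, bytearray], rec: TranscriptRecord, insert: str, rng) -> tuple[int, int]:
    """Write ``insert`` into one exon of ``rec``; returns genomic interval used."""
    fitting = [(a, b) for a, b in rec.exons if b - a >= len(insert) + 20]
    if not fitting:
        a, b = max(rec.exons, key=lambda e: e[1] - e[0])
        insert = insert[: (b - a) - 20]
        fitting = [(a, b)]
    a, b = fitting[int(rng.integers(0, len(fitting)))]
    off = int(rng.integers(10, (b - a) - len(insert) - 9))
    genome[rec.chromosome][a + off : a + off + len(insert)] = insert.encode()
    return (a + off, a + off + len(insert))


def _mimic_site(rng: np.random.Generator, mirna: str, bulge_at: int = 10) -> str:
    """Perfect-complement mimic site with a 3-nt bulge opposite positions 9-12.

    Reading the site 5'->3': complement of miRNA positions ``bulge_at``..L,
    then 3 unpaired nucleotides, then complement of positions 1..bulge_at-1.
    """
    bulge = "".join(chr(c) for c in rng.choice(_BASES, size=3).view(np.uint8))
    return revcomp(mirna[bulge_at - 1 :]) + bulge + revcomp(mirna[: bulge_at - 1])


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SyntheticConfig) -> SyntheticBundle:
    """Build genome, annotation, libraries and the truth table."""
    rng = np.random.default_rng([config.seed, 0])

    # --- libraries ---------------------------------------------------------
    te_library: dict[str, str] = {}
    for i, family in enumerate(TE_FAMILIES):
        length = int(rng.integers(300, 600))
        te_library[f"TE_{family}_{i + 1}"] = bytes(
            _random_seq(rng, length).view(np.uint8)
        ).decode()
    mirna_library: dict[str, str] = {}
    hairpin_library: dict[str, str] = {}
    for i in range(5):
        mature = bytes(_random_seq(rng, 21).view(np.uint8)).decode()
        name = f"miR{i + 1:03d}"
        mirna_library[name] = mature
        arm5 = bytes(_random_seq(rng, 50).view(np.uint8)).decode()
        arm3 = bytes(_random_seq(rng, 40).view(np.uint8)).decode()
        hairpin_library[f"{name}_hairpin"] = arm5 + mature + revcomp(mature)[:18] + arm3

    # --- lincRNA roles -----------------------------------------------------
    roles = (
        ["rna_rna"] * config.n_planted_rnarna_pairs
        + ["pa"] * config.n_planted_pa_pairs
        + ["rna_dna"] * config.n_planted_dna_pairs
        + ["neighbor"] * config.n_planted_neighbors
        + ["te"] * config.n_te_insertions
        + ["mimic"] * config.n_mimic_sites
    )
    if len(roles) > config.n_lincRNAs:
        raise SizingError(
            f"{len(roles)} planted lincRNA roles exceed n_lincRNAs={config.n_lincRNAs}"
        )
    roles += ["null"] * (config.n_lincRNAs - len(roles))
    roles = [roles[i] for i in rng.permutation(len(roles))]

    # --- feature layout ----------------------------------------------------
    stream: list[tuple[str, int]] = [("coding", i) for i in range(config.n_coding_genes)]
    stream += [("linc", i) for i in range(config.n_lincRNAs)]
    stream = [stream[i] for i in rng.permutation(len(stream))]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.n_chromosomes == 0 and stream:
        raise SizingError("no chromosomes configured")
    chunks: list[list[tuple[str, int]]] = [[] for _ in chrom_names]
    for k, item in enumerate(stream):
        chunks[k % max(len(chunks), 1)].append(item)

    reference: list[TranscriptRecord] = []
    lincs: list[TranscriptRecord] = []
    linc_role: dict[str, str] = {}
    for chrom, chunk in zip(chrom_names, chunks):
        cursor = 3000
        for kind, idx in chunk:
            if kind == "coding":
                cursor += int(rng.integers(600, 1500)) + 2000  # promoter reserve
                n_ex = int(rng.integers(2, 5))
                exons = []
                pos = cursor
                for e in range(n_ex):
                    elen = int(rng.integers(200, 500))
                    exons.append((pos, pos + elen))
                    pos += elen + int(rng.integers(100, 250))
                pos = exons[-1][1]
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"AT{chrom[3:]}G{(idx + 1) * 10:05d}"
                reference.append(
                    TranscriptRecord(id=gid, chromosome=chrom, strand=strand, exons=exons, biotype="coding")
                )
                cursor = pos + 2000  # downstream reserve (promoter of '-' genes)
            else:
                role = roles[idx]
                cursor += int(rng.integers(600, 1500))
                if role in ("rna_rna", "pa", "mimic", "rna_dna"):
                    strand = "+"
                    elen = int(rng.integers(max(600, config.planted_duplex_length + 60), 1001))
                    exons = [(cursor, cursor + elen)]
                elif rng.random() < 1 / 3:
                    strand = "+" if rng.random() < 0.5 else "-"
                    e1 = int(rng.integers(250, 500))
                    e2 = int(rng.integers(250, 500))
                    gap = int(rng.integers(100, 200))
                    exons = [(cursor, cursor + e1), (cursor + e1 + gap, cursor + e1 + gap + e2)]
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                    elen = int(rng.integers(400, 900))
                    exons = [(cursor, cursor + elen)]
                lid = f"XLOC_{idx + 1:06d}"
                rec = TranscriptRecord(
                    id=lid, chromosome=chrom, strand=strand, exons=exons, biotype="lincRNA_candidate"
                )
                lincs.append(rec)
                linc_role[lid] = role
                cursor = exons[-1][1]
            if cursor > config.chromosome_length - 2000:
                raise SizingError(
                    f"features overflow {chrom} ({cursor} > {config.chromosome_length - 2000}); "
                    "increase chromosome_length or reduce feature counts"
                )

    # decoy de novo transcripts inside gene introns (removed by classification)
    decoys: list[TranscriptRecord] = []
    multi_exon = [g for g in reference if len(g.exons) >= 2]
    n_decoys = max(2, config.n_lincRNAs // 4) if multi_exon else 0
    for i in range(n_decoys):
        host = multi_exon[int(rng.integers(0, len(multi_exon)))]
        ia, ib = host.introns[0]
        if ib - ia < 60:
            continue
        a = ia + 5
        b = min(ib - 5, a + int(rng.integers(50, max(51, ib - ia - 10))))
        decoys.append(
            TranscriptRecord(
                id=f"XLOC_D{i + 1:04d}",
                chromosome=host.chromosome,
                strand="+" if rng.random() < 0.5 else "-",
                exons=[(a, b)],
                biotype="lincRNA_candidate",
            )
        )

    # --- genome ------------------------------------------------------------
    genome: dict[str, bytearray] = {
        chrom: bytearray(bytes(_random_seq(rng, config.chromosome_length).view(np.uint8)))
        for chrom in chrom_names
    }

    # --- plantings ---------------------------------------------------------
    truth = TruthTable()
    by_role: dict[str, list[TranscriptRecord]] = {}
    for rec in lincs:
        by_role.setdefault(linc_role[rec.id], []).append(rec)
    gene_pool = [reference[i] for i in rng.permutation(len(reference))]
    pool_pos = 0

    def _next_genes(k: int) -> list[TranscriptRecord]:
        nonlocal pool_pos
        if pool_pos + k > len(gene_pool):
            raise SizingError("not enough coding genes for the requested plantings")
        out = gene_pool[pool_pos : pool_pos + k]
        pool_pos += k
        return out

    D = config.planted_duplex_length

    def _plant_duplex(linc: TranscriptRecord, target: TranscriptRecord) -> None:
        mrna = target.splice({c: bytes(s).decode() for c, s in genome.items()})
        off = int(rng.integers(0, max(1, len(mrna) - D)))
        segment = mrna[off : off + D]
        planted = _mutate(rng, revcomp(segment), config.planted_identity)
        a, b = _embed(genome, linc, planted, rng)
        ex_a = linc.exons[0][0]
        truth.duplex_intervals[linc.id] = (a - ex_a, b - ex_a)  # transcript coords ('+', 1 exon)
        truth.target_duplex_intervals[(linc.id, target.id)] = (off, off + D)

    for k, linc in enumerate(by_role.get("rna_rna", [])):
        (target,) = _next_genes(1)
        _plant_duplex(linc, target)
        direction = "positive" if k % 2 == 0 else "negative"
        truth.planted_pairs.append(PlantedPair(linc.id, target.id, "rna_rna", direction))

    for linc in by_role.get("pa", []):
        (target,) = _next_genes(1)
        _plant_duplex(linc, target)
        truth.planted_pa_pairs.append(PlantedPair(linc.id, target.id, "rna_rna", "positive"))

    for k, linc in enumerate(by_role.get("rna_dna", [])):
        (target,) = _next_genes(1)
        # source segment from the target's promoter window (upstream of TSS)
        if target.strand == "+":
            p0, p1 = max(0, target.start - 2000), target.start
        else:
            p0, p1 = target.end, min(config.chromosome_length, target.end + 2000)
        off = p0 + int(rng.integers(0, max(1, (p1 - p0) - D)))
        segment = bytes(genome[target.chromosome][off : off + D]).decode()
        if rng.random() < 0.5:
            segment = revcomp(segment)
        planted = _mutate(rng, segment, config.planted_identity)
        a, b = _embed(genome, linc, planted, rng)
        ex_a = linc.exons[0][0]
        truth.duplex_intervals.setdefault(linc.id, (a - ex_a, b - ex_a))
        direction = "positive" if k % 2 == 0 else "negative"
        truth.planted_pairs.append(PlantedPair(linc.id, target.id, "rna_dna", direction))

    used_targets = {p.target_id for p in truth.planted_pairs + truth.planted_pa_pairs}
    for k, linc in enumerate(by_role.get("neighbor", [])):
        near = [
            (min(abs(g.start - linc.end), abs(linc.start - g.end)), g.id)
            for g in reference
            if g.chromosome == linc.chromosome
        ]
        near.sort()
        in_window = [(d, gid) for d, gid in near if d <= 10_000]
        if not in_window:
            raise SizingError(f"no gene within 10 kb of planted neighbor lincRNA {linc.id}")
        # prefer a gene not already serving as a planted target elsewhere
        unused = [(d, gid) for d, gid in in_window if gid not in used_targets]
        _, gid = (unused or in_window)[0]
        used_targets.add(gid)
        direction = "positive" if k % 2 == 0 else "negative"
        truth.planted_pairs.append(PlantedPair(linc.id, gid, "neighbor", direction))

    te_ids = sorted(te_library)
    for linc in by_role.get("te", []):
        te_id = te_ids[int(rng.integers(0, max(1, len(te_ids) - 1)))]  # reserve last for promoters
        element = te_library[te_id]
        frag_len = int(rng.integers(150, min(300, len(element))))
        start = int(rng.integers(0, len(element) - frag_len + 1))
        _embed(genome, linc, element[start : start + frag_len], rng)
        truth.planted_te.append((linc.id, te_id))
    if config.n_te_insertions > 0 and pool_pos + 2 <= len(gene_pool):
        promoter_te = te_library[te_ids[-1]]
        for target in _next_genes(2):
            frag = promoter_te[: min(250, len(promoter_te))]
            if target.strand == "+":
                p0 = max(0, target.start - 1500)
            else:
                p0 = target.end + 200
            genome[target.chromosome][p0 : p0 + len(frag)] = frag.encode()

    mir_ids = sorted(mirna_library)
    for i, linc in enumerate(by_role.get("mimic", [])):
        mir_id = mir_ids[i % len(mir_ids)]
        site = _mimic_site(rng, mirna_library[mir_id])
        a, b = _embed(genome, linc, site, rng)
        truth.planted_mimics.append((linc.id, mir_id, a - linc.exons[0][0]))

    rnarna_lincs = [p.lincrna_id for p in truth.planted_pairs if p.interaction == "rna_rna"]
    truth.planted_sirna_precursors = rnarna_lincs[: math.ceil(len(rnarna_lincs) / 2)]

    # --- finalize ----------------------------------------------------------
    genome_str = {chrom: bytes(s).decode() for chrom, s in genome.items()}
    reference = [r.with_sequence(genome_str) for r in reference]
    denovo = sorted(
        [r.with_sequence(genome_str) for r in lincs + decoys],
        key=lambda r: (r.chromosome, r.start, r.id),
    )
    reference.sort(key=lambda r: (r.chromosome, r.start, r.id))

    conservation: list[tuple[str, int, int, float]] = []
    for rec in reference:
        for a, b in rec.exons:
            conservation.append((rec.chromosome, a, b, float(np.clip(rng.normal(0.75, 0.05), 0, 1))))
    for rec in lincs:
        for a, b in rec.exons:
            conservation.append((rec.chromosome, a, b, float(np.clip(rng.normal(0.30, 0.05), 0, 1))))
    conservation.sort()

    return SyntheticBundle(
        genome=genome_str,
        reference=reference,
        denovo=denovo,
        te_library=te_library,
        mirna_library=mirna_library,
        hairpin_library=hairpin_library,
        truth=truth,
        conservation_intervals=conservation,
    )


# ---------------------------------------------------------------------------
# counts


def _contrast_shape(rng: np.random.Generator, n_cond: int, i_a: int, i_b: int) -> np.ndarray:
    """Unit condition profile: +-1/2 on the designated contrast, noise elsewhere.

    Multiplying by a log effect size yields that exact fold change on the
    designated contrast plus correlated variation across the other conditions,
    so paired loci sharing a shape correlate strongly across the full design.
    """
    shape = rng.normal(0.0, 0.45, n_cond)
    shape[i_a] = 0.5
    shape[i_b] = -0.5
    return shape


def generate_counts(bundle: SyntheticBundle, config: SyntheticConfig) -> tuple[CountMatrix, CountMatrix]:
    """Negative-binomial total and polysomal count matrices with planted effects.

    Planted steady-state pairs share a condition profile (sign-flipped for
    negative pairs) scaled to ``fold_change_effect`` on the designated
    contrast; polysome-association pairs put the scaled profile on the
    lincRNA's steady state and a ``pa_effect``-scaled copy on the target's
    polysomal fraction only. All other loci are null. Library size factors are
    log-uniform in [0.5, 2].
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = bundle.truth
    conds = config.conditions
    i_a = conds.index(config.designated_contrast[0])
    i_b = conds.index(config.designated_contrast[1])
    loci = [r.id for r in bundle.reference] + [r.id for r in bundle.denovo]
    idx = {lid: k for k, lid in enumerate(loci)}
    n_loci, n_cond = len(loci), len(conds)

    base_mu = 10 ** rng.uniform(1.3, 2.7, n_loci)
    pa_ratio = np.exp(rng.normal(0.0, 0.3, n_loci))
    eff_total = np.zeros((n_loci, n_cond))
    eff_polysomal_extra = np.zeros((n_loci, n_cond))
    log_fc = math.log(config.fold_change_effect)
    log_pa = math.log(config.pa_effect)

    # Balance the overall sign of the planted profiles so the panel carries
    # about as many up- as down-regulated loci in the designated condition
    # (as real designs do); a one-sided panel of planted effects would bias
    # the median-of-ratios size factors on a miniature locus set. The greedy
    # counter keeps the up-minus-down locus imbalance within +-2.
    balance = 0
    for pair in truth.planted_pairs:
        overall = -1.0 if balance > 0 else 1.0
        shape = _contrast_shape(rng, n_cond, i_a, i_b) * overall
        sign = 1.0 if pair.direction == "positive" else -1.0
        eff_total[idx[pair.lincrna_id]] += shape * log_fc
        eff_total[idx[pair.target_id]] += sign * shape * log_fc
        balance += int(overall) + int(overall * sign)
    for pair in truth.planted_pa_pairs:
        overall = -1.0 if balance > 0 else 1.0
        shape = _contrast_shape(rng, n_cond, i_a, i_b) * overall
        sign = 1.0 if pair.direction == "positive" else -1.0
        eff_total[idx[pair.lincrna_id]] += shape * log_fc
        eff_polysomal_extra[idx[pair.target_id]] += sign * shape * log_pa
        balance += int(overall)

    n_rep = config.n_replicates
    sample_names_t = [f"{c}_total_rep{r + 1}" for c in conds for r in range(n_rep)]
    sample_names_p = [f"{c}_polysomal_rep{r + 1}" for c in conds for r in range(n_rep)]
    sf_t = np.exp(rng.uniform(math.log(0.5), math.log(2.0), len(sample_names_t)))
    sf_p = np.exp(rng.uniform(math.log(0.5), math.log(2.0), len(sample_names_p)))

    def _draw(mean_matrix: np.ndarray) -> np.ndarray:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean_matrix)
        return rng.negative_binomial(r, p)

    cond_of_sample = np.repeat(np.arange(n_cond), n_rep)
    mu_t = base_mu[:, None] * np.exp(eff_total[:, cond_of_sample]) * sf_t[None, :]
    mu_p = (
        base_mu[:, None]
        * pa_ratio[:, None]
        * np.exp((eff_total + eff_polysomal_extra)[:, cond_of_sample])
        * sf_p[None, :]
    )
    total = make_count_matrix(_draw(mu_t), loci, sample_names_t)
    polysomal = make_count_matrix(_draw(mu_p), loci, sample_names_p)
    return total, polysomal


# ---------------------------------------------------------------------------
# small reads


_READ_LENGTHS = np.arange(18, 29)
_READ_LENGTH_WEIGHTS = np.array([3, 3, 5, 8, 10, 14, 30, 12, 7, 4, 4], dtype=float)
_READ_LENGTH_WEIGHTS /= _READ_LENGTH_WEIGHTS.sum()


def generate_small_reads(bundle: SyntheticBundle, config: SyntheticConfig) -> list[tuple[str, str]]:
    """Simulated 18-28-nt small-RNA reads (length mode 24).

    Background reads are uniform over lincRNA and mRNA transcripts at
    ``background_read_density`` reads/nt; designated siRNA-precursor lincRNAs
    additionally receive ``sirna_hotspot_reads`` reads confined to their duplex
    region, and their targets a quarter of that in the complementary segment
    (the weaker target-side enrichment seen in real siRNA data).
    """
    rng = np.random.default_rng([config.seed, 2])
    truth = bundle.truth
    reads: list[tuple[str, str]] = []
    counter = 0

    def _emit(seq: str) -> None:
        nonlocal counter
        counter += 1
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"sr{counter:06d}", seq))

    def _read_from(seq: str, lo: int, hi: int, n: int) -> None:
        # n reads with start positions uniform in [lo, hi)
        for _ in range(n):
            rl = int(rng.choice(_READ_LENGTHS, p=_READ_LENGTH_WEIGHTS))
            rl = min(rl, hi - lo)
            start = int(rng.integers(lo, max(lo + 1, hi - rl + 1)))
            _emit(seq[start : start + rl])

    transcripts = {r.id: r for r in bundle.denovo + bundle.reference}
    for rec in sorted(transcripts.values(), key=lambda r: r.id):
        seq = rec.sequence or ""
        if len(seq) < 28:
            continue
        n_bg = int(rng.poisson(len(seq) * config.background_read_density))
        _read_from(seq, 0, len(seq), n_bg)

    precursor_targets = {
        p.lincrna_id: p.target_id
        for p in truth.planted_pairs + truth.planted_pa_pairs
        if p.interaction == "rna_rna"
    }
    for linc_id in truth.planted_sirna_precursors:
        rec = transcripts[linc_id]
        a, b = truth.duplex_intervals[linc_id]
        _read_from(rec.sequence, a, b, config.sirna_hotspot_reads)
        target_id = precursor_targets.get(linc_id)
        key = (linc_id, target_id)
        if target_id and key in truth.target_duplex_intervals:
            ta, tb = truth.target_duplex_intervals[key]
            _read_from(transcripts[target_id].sequence, ta, tb, config.sirna_hotspot_reads // 4)
    return reads
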