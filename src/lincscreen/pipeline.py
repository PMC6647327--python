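"""End-to-end orchestration: from a (synthetic or on-disk) bundle to calls.

``run_pipeline`` executes the stages in dependency order — catalog
classification, normalization, differential expression and polysome shifts
per contrast, the four homology screens, the regulatory screens, small-RNA
profiles and the miRNA screens — writes every table as TSV under the output
directory, and stamps each output row with a hash of the threshold manifest
so any result can be traced to the exact configuration that produced it.

Every threshold defaults to the screen's published value and reaches the
stages only through :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, catalog, expression, mirna, screens, simulate, smallrna
from .catalog import ConservationTrack, TranscriptRecord
from .expression import CountMatrix
from .io import read_fasta, read_fastx_reads, write_bedgraph, write_fasta, write_tsv
from .simulate import PlantedPair, SyntheticBundle, SyntheticConfig, TruthTable


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds in one serializable object."""

    outdir: str = "lincscreen_out"
    seed: int = 0
    # screen thresholds (published defaults)
    fc_thresh: float = 2.0
    padj_thresh: float = 0.1
    pa_thresh: float = 1.3
    evalue_rna: float = 1.0
    min_len_rna: int = 100
    evalue_dna: float = 1.0
    min_len_dna: int = 100
    evalue_te: float = 1e-12
    min_len_te: int = 50
    evalue_hairpin: float = 1e-4
    min_len_hairpin: int = 50
    promoter_len: int = 2000
    neighbor_window: int = 10_000
    count_floor: float = 10.0
    pearson_robust: float = 0.6
    sirna_unique_min: int = 5
    sirna_enrich_min: float = 2.0
    read_len_min: int = 18
    read_len_max: int = 28
    expectation_max: float = 3.0
    mimic_max_mismatch_gu: int = 3
    word_size: int = 9
    # inputs: either a bundle directory on disk, or a synthetic configuration
    bundle_dir: str | None = None
    synthetic: dict | None = None
    contrasts: list | None = None

    THRESHOLD_FIELDS = (
        "fc_thresh", "padj_thresh", "pa_thresh", "evalue_rna", "min_len_rna",
        "evalue_dna", "min_len_dna", "evalue_te", "min_len_te", "evalue_hairpin",
        "min_len_hairpin", "promoter_len", "neighbor_window", "count_floor",
        "pearson_robust", "sirna_unique_min", "sirna_enrich_min", "read_len_min",
        "read_len_max", "expectation_max", "mimic_max_mismatch_gu", "word_size",
    )

    def threshold_manifest(self) -> dict:
        return {name: getattr(self, name) for name in self.THRESHOLD_FIELDS}

    def manifest_hash(self) -> str:
        payload = json.dumps(self.threshold_manifest(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.contrasts is not None:
            cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def synthetic_config(self) -> SyntheticConfig | None:
        if self.synthetic is None:
            return None
        params = dict(self.synthetic)
        params.setdefault("seed", self.seed)
        return SyntheticConfig(**params)


# ---------------------------------------------------------------------------
# bundle I/O

BUNDLE_FILES = {
    "genome": "genome.fa",
    "reference": "reference.gtf",
    "denovo": "denovo.gtf",
    "te": "te_library.fa",
    "mirna": "mirna_mature.fa",
    "hairpin": "mirna_hairpins.fa",
    "total": "counts_total.tsv",
    "polysomal": "counts_polysomal.tsv",
    "reads": "small_reads.fa",
    "conservation": "conservation.bedGraph",
}


@dataclass
class Bundle:
    """Everything the pipeline consumes, in memory."""

    genome: dict[str, str]
    reference: list[TranscriptRecord]
    denovo: list[TranscriptRecord]
    te_library: dict[str, str]
    mirna_library: dict[str, str]
    hairpin_library: dict[str, str]
    total: CountMatrix
    polysomal: CountMatrix
    reads: list[tuple[str, str]]
    conservation: ConservationTrack | None = None
    truth: TruthTable | None = None


def simulate_bundle(config: SyntheticConfig) -> Bundle:
    ann = simulate.generate_annotation(config)
    total, polysomal = simulate.generate_counts(ann, config)
    reads = simulate.generate_small_reads(ann, config)
    return Bundle(
        genome=ann.genome,
        reference=ann.reference,
        denovo=ann.denovo,
        te_library=ann.te_library,
        mirna_library=ann.mirna_library,
        hairpin_library=ann.hairpin_library,
        total=total,
        polysomal=polysomal,
        reads=reads,
        conservation=ann.conservation_track(),
        truth=ann.truth,
    )


def write_bundle(bundle: Bundle, outdir: str | os.PathLike, ann: SyntheticBundle | None = None) -> Path:
    """Write a bundle as plain-text files (deterministic byte layout)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, out / BUNDLE_FILES["genome"])
    catalog.write_gtf(bundle.reference, out / BUNDLE_FILES["reference"])
    catalog.write_gtf(bundle.denovo, out / BUNDLE_FILES["denovo"])
    write_fasta(bundle.te_library, out / BUNDLE_FILES["te"])
    write_fasta(bundle.mirna_library, out / BUNDLE_FILES["mirna"])
    write_fasta(bundle.hairpin_library, out / BUNDLE_FILES["hairpin"])
    bundle.total.to_tsv(out / BUNDLE_FILES["total"])
    bundle.polysomal.to_tsv(out / BUNDLE_FILES["polysomal"])
    write_fasta(dict(bundle.reads), out / BUNDLE_FILES["reads"])
    if ann is not None and ann.conservation_intervals:
        write_bedgraph(ann.conservation_intervals, out / BUNDLE_FILES["conservation"])
    if bundle.truth is not None:
        t = bundle.truth
        write_tsv(
            pd.DataFrame([dataclasses.asdict(p) for p in t.planted_pairs]),
            out / "truth_pairs.tsv",
        )
        write_tsv(
            pd.DataFrame([dataclasses.asdict(p) for p in t.planted_pa_pairs]),
            out / "truth_pa_pairs.tsv",
        )
        write_tsv(
            pd.DataFrame(t.planted_mimics, columns=["lincrna_id", "mirna_id", "position"]),
            out / "truth_mimics.tsv",
        )
        write_tsv(pd.DataFrame(t.planted_te, columns=["lincrna_id", "te_id"]), out / "truth_te.tsv")
        write_tsv(
            pd.DataFrame({"lincrna_id": t.planted_sirna_precursors}),
            out / "truth_sirna_precursors.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [(k, a, b) for k, (a, b) in sorted(t.duplex_intervals.items())],
                columns=["lincrna_id", "start", "end"],
            ),
            out / "truth_duplex_intervals.tsv",
        )
    return out


def load_bundle(bundle_dir: str | os.PathLike) -> Bundle:
    """Load a bundle directory; fails fast naming any missing file."""
    d = Path(bundle_dir)
    for key in ("genome", "reference", "denovo", "te", "mirna", "hairpin", "total", "polysomal", "reads"):
        if not (d / BUNDLE_FILES[key]).exists():
            raise FileNotFoundError(f"missing bundle input: {d / BUNDLE_FILES[key]}")
    genome = read_fasta(d / BUNDLE_FILES["genome"])
    reference = catalog.read_gtf(d / BUNDLE_FILES["reference"], genome=genome)
    denovo = catalog.read_gtf(d / BUNDLE_FILES["denovo"], genome=genome)
    conservation = None
    if (d / BUNDLE_FILES["conservation"]).exists():
        conservation = ConservationTrack.from_bedgraph(d / BUNDLE_FILES["conservation"])
    truth = None
    if (d / "truth_pairs.tsv").exists():
        truth = TruthTable()
        pairs = pd.read_csv(d / "truth_pairs.tsv", sep="\t")
        truth.planted_pairs = [PlantedPair(**row) for row in pairs.to_dict("records")]
        if (d / "truth_pa_pairs.tsv").exists():
            pa = pd.read_csv(d / "truth_pa_pairs.tsv", sep="\t")
            truth.planted_pa_pairs = [PlantedPair(**row) for row in pa.to_dict("records")]
        if (d / "truth_mimics.tsv").exists():
            truth.planted_mimics = [
                tuple(r) for r in pd.read_csv(d / "truth_mimics.tsv", sep="\t").itertuples(index=False)
            ]
        if (d / "truth_te.tsv").exists():
            truth.planted_te = [
                tuple(r) for r in pd.read_csv(d / "truth_te.tsv", sep="\t").itertuples(index=False)
            ]
        if (d / "truth_sirna_precursors.tsv").exists():
            truth.planted_sirna_precursors = list(
                pd.read_csv(d / "truth_sirna_precursors.tsv", sep="\t")["lincrna_id"]
            )
        if (d / "truth_duplex_intervals.tsv").exists():
            dup = pd.read_csv(d / "truth_duplex_intervals.tsv", sep="\t")
            truth.duplex_intervals = {
                r.lincrna_id: (int(r.start), int(r.end)) for r in dup.itertuples(index=False)
            }
    return Bundle(
        genome=genome,
        reference=reference,
        denovo=denovo,
        te_library=read_fasta(d / BUNDLE_FILES["te"]),
        mirna_library=read_fasta(d / BUNDLE_FILES["mirna"]),
        hairpin_library=read_fasta(d / BUNDLE_FILES["hairpin"]),
        total=CountMatrix.from_tsv(d / BUNDLE_FILES["total"]),
        polysomal=CountMatrix.from_tsv(d / BUNDLE_FILES["polysomal"]),
        reads=read_fastx_reads(d / BUNDLE_FILES["reads"]),
        conservation=conservation,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# stages


def default_contrasts(mat: CountMatrix) -> list[tuple[str, str]]:
    conds = mat.conditions()
    if set(simulate.CONDITIONS_12) <= set(conds):
        return list(simulate.CONTRASTS_12)
    return [(c, conds[0]) for c in conds[1:]]


@dataclass
class PipelineResult:
    outdir: Path
    config: PipelineConfig
    bundle: Bundle
    lincrnas: list[TranscriptRecord]
    features: pd.DataFrame
    neighbors: list
    norm_total: CountMatrix
    norm_polysomal: CountMatrix
    de_tables: dict
    pa_tables: dict
    hits_rna: list
    hits_dna: list
    hits_te: list
    hits_hairpin: list
    calls: pd.DataFrame
    profiles: pd.DataFrame
    precursors: pd.DataFrame
    mimics: pd.DataFrame
    binding_sites: pd.DataFrame
    nodes: pd.DataFrame
    edges: pd.DataFrame
    summary: pd.DataFrame


def _check_locus_ids(bundle: Bundle) -> None:
    known = {r.id for r in bundle.reference} | {r.id for r in bundle.denovo}
    for name, mat in (("total", bundle.total), ("polysomal", bundle.polysomal)):
        missing = sorted(set(mat.loci) - known)
        if missing:
            raise ValueError(
                f"{name} count matrix carries loci absent from the annotation: {missing[:10]}"
            )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs and write the result tables."""
    syn = config.synthetic_config()
    if syn is not None:
        bundle = simulate_bundle(syn)
    elif config.bundle_dir is not None:
        bundle = load_bundle(config.bundle_dir)
    else:
        raise ValueError("configure either `synthetic` or `bundle_dir`")
    _check_locus_ids(bundle)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.manifest_hash()

    # --- catalog ----------------------------------------------------------
    lincrnas = catalog.classify_intergenic(
        bundle.denovo, bundle.reference, chromosomes=set(bundle.genome)
    )
    features = pd.DataFrame(
        [dataclasses.asdict(catalog.transcript_features(t, bundle.conservation)) for t in lincrnas]
    )
    neighbors = []
    for linc in lincrnas:
        neighbors.extend(catalog.neighbor_scan(linc, bundle.reference, window=config.neighbor_window))

    # --- expression -------------------------------------------------------
    norm_total = expression.normalize_counts(bundle.total)
    norm_polysomal = expression.normalize_counts(bundle.polysomal)
    contrasts = [tuple(c) for c in (config.contrasts or default_contrasts(bundle.total))]
    de_tables = {c: expression.differential_expression(norm_total, c) for c in contrasts}
    pa_tables = {c: expression.polysome_shift(norm_total, norm_polysomal, c) for c in contrasts}

    # --- homology screens -------------------------------------------------
    scheme = align.ScoringScheme()
    hits_rna = align.scan_trans_nat(
        lincrnas, bundle.reference, scheme,
        min_len=config.min_len_rna, max_e=config.evalue_rna, word_size=config.word_size,
    )
    hits_dna = align.scan_dna_targets(
        lincrnas, bundle.reference, bundle.genome, scheme,
        promoter_len=config.promoter_len, min_len=config.min_len_dna,
        max_e=config.evalue_dna, word_size=config.word_size,
    )
    hits_te = align.scan_library(
        lincrnas, bundle.te_library, scheme,
        max_e=config.evalue_te, min_len=config.min_len_te, word_size=config.word_size,
    ) if bundle.te_library else []
    hits_hairpin = align.scan_library(
        lincrnas, bundle.hairpin_library, scheme,
        max_e=config.evalue_hairpin, min_len=config.min_len_hairpin, word_size=config.word_size,
    ) if bundle.hairpin_library else []

    # --- regulatory screens ------------------------------------------------
    common = dict(fc_thresh=config.fc_thresh, padj_thresh=config.padj_thresh,
                  robust_r=config.pearson_robust)
    calls_ss = screens.screen_steady_state(
        hits_rna, de_tables, norm_total, interaction="rna_rna",
        floor=config.count_floor, **common,
    )
    calls_dna = screens.screen_steady_state(
        hits_dna, de_tables, norm_total, interaction="rna_dna",
        floor=config.count_floor, **common,
    )
    calls_tr = screens.screen_translation(
        hits_rna, de_tables, pa_tables, norm_total, norm_polysomal,
        pa_thresh=config.pa_thresh, **common,
    )
    calls_nb = screens.screen_neighbors(neighbors, de_tables, norm_total, **common)
    calls_tr = calls_tr.assign(interaction="rna_rna_pa")
    calls = pd.concat([calls_ss, calls_dna, calls_tr, calls_nb], ignore_index=True)

    # --- small RNA ---------------------------------------------------------
    comp_by_transcript: dict[str, list[tuple[int, int]]] = {}
    for h in hits_rna:
        comp_by_transcript.setdefault(h.query_id, []).append(h.query_interval)
        comp_by_transcript.setdefault(h.subject_id, []).append(h.subject_interval)
    mapped_targets = [t for t in lincrnas + bundle.reference if t.id in comp_by_transcript]
    profiles_map = smallrna.map_small_reads(
        bundle.reads, mapped_targets, min_len=config.read_len_min, max_len=config.read_len_max
    )
    prof_rows, prec_rows = [], []
    linc_ids = {t.id for t in lincrnas}
    for tid in sorted(profiles_map):
        prof, call = smallrna.score_profile(
            profiles_map[tid],
            comp_by_transcript.get(tid, []),
            min_unique=config.sirna_unique_min,
            min_enrichment=config.sirna_enrich_min,
        )
        prof_rows.append(
            {
                "transcript": tid,
                "kind": "lincRNA" if tid in linc_ids else "target",
                "length": prof.length,
                "mapped_reads": prof.total_mapped,
                "reads_in_comp": prof.reads_in_comp,
                "unique_reads_in_comp": prof.unique_reads_in_comp,
                "density_comp": prof.density_comp,
                "density_noncomp": prof.density_noncomp,
                "enrichment": prof.enrichment,
            }
        )
        if tid in linc_ids:
            prec_rows.append(
                {
                    "transcript": tid,
                    "is_precursor": call.is_precursor,
                    "unique_reads_ok": call.unique_reads_ok,
                    "enrichment_ok": call.enrichment_ok,
                }
            )
    profiles = pd.DataFrame(prof_rows)
    precursors = pd.DataFrame(prec_rows)

    # --- miRNA screens -----------------------------------------------------
    mimic_rows, site_rows = [], []
    for linc in lincrnas:
        for mid in sorted(bundle.mirna_library):
            for call in mirna.find_mimic_sites(
                linc.sequence, bundle.mirna_library[mid],
                lincrna_id=linc.id, mirna_id=mid,
                max_mismatch_gu=config.mimic_max_mismatch_gu,
            ):
                mimic_rows.append(
                    {
                        "lincrna": linc.id,
                        "mirna": mid,
                        "site_start": call.site_start + 1,  # 1-based in outputs
                        "site_end": call.site_end,
                        "n_mismatch_plus_gu": call.n_mismatch_plus_gu,
                    }
                )
            for site in mirna.find_binding_sites(
                linc.sequence, bundle.mirna_library[mid],
                lincrna_id=linc.id, mirna_id=mid, expectation_max=config.expectation_max,
            ):
                site_rows.append(
                    {
                        "lincrna": linc.id,
                        "mirna": mid,
                        "site_start": site.site_start + 1,
                        "site_end": site.site_end,
                        "expectation": site.expectation,
                        "upe_not_evaluated": site.upe_not_evaluated,
                    }
                )
    mimics = pd.DataFrame(mimic_rows, columns=["lincrna", "mirna", "site_start", "site_end", "n_mismatch_plus_gu"])
    binding_sites = pd.DataFrame(
        site_rows, columns=["lincrna", "mirna", "site_start", "site_end", "expectation", "upe_not_evaluated"]
    )

    # --- network + summary -------------------------------------------------
    nodes, edges = screens.build_network(calls, norm_total)
    transnat_ids = sorted({h.query_id for h in hits_rna})
    summary = summarize_counts(
        calls, de_tables, sorted(linc_ids), transnat_ids,
        fc_thresh=config.fc_thresh, padj_thresh=config.padj_thresh,
    )

    # --- write -------------------------------------------------------------
    def _out(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df["config_hash"] = chash
        write_tsv(df, outdir / name)

    _out(features, "lincrna_features.tsv")
    _out(
        pd.DataFrame([dataclasses.asdict(n) for n in neighbors],
                     columns=["lincrna_id", "gene_id", "index", "distance"]),
        "neighbors.tsv",
    )
    de_all = pd.concat(
        [t.reset_index().assign(contrast=screens._contrast_label(c)) for c, t in de_tables.items()],
        ignore_index=True,
    ) if de_tables else pd.DataFrame()
    pa_all = pd.concat(
        [t.reset_index().assign(contrast=screens._contrast_label(c)) for c, t in pa_tables.items()],
        ignore_index=True,
    ) if pa_tables else pd.DataFrame()
    _out(de_all, "differential_expression.tsv")
    _out(pa_all, "polysome_shift.tsv")
    _out(align.hits_to_frame(hits_rna), "hits_trans_nat.tsv")
    _out(align.hits_to_frame(hits_dna), "hits_dna_targets.tsv")
    _out(align.hits_to_frame(hits_te), "hits_te.tsv")
    _out(align.hits_to_frame(hits_hairpin), "hits_hairpin.tsv")
    _out(calls, "pair_calls.tsv")
    _out(profiles, "sirna_profiles.tsv")
    _out(precursors, "sirna_precursors.tsv")
    _out(mimics, "mimic_sites.tsv")
    _out(binding_sites, "mirna_binding_sites.tsv")
    _out(nodes, "network_nodes.tsv")
    _out(edges, "network_edges.tsv")
    _out(summary, "summary.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"hash": chash, "thresholds": config.threshold_manifest()}, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config.yaml")

    return PipelineResult(
        outdir=outdir, config=config, bundle=bundle, lincrnas=lincrnas, features=features,
        neighbors=neighbors, norm_total=norm_total, norm_polysomal=norm_polysomal,
        de_tables=de_tables, pa_tables=pa_tables, hits_rna=hits_rna, hits_dna=hits_dna,
        hits_te=hits_te, hits_hairpin=hits_hairpin, calls=calls, profiles=profiles,
        precursors=precursors, mimics=mimics, binding_sites=binding_sites,
        nodes=nodes, edges=edges, summary=summary,
    )


def summarize_counts(
    calls: pd.DataFrame,
    de_tables: dict,
    lincrna_ids: list[str],
    transnat_ids: list[str],
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.1,
) -> pd.DataFrame:
    """Per-contrast counts of regulated lincRNAs and trans-NATs.

    The final row counts unique genes: a lincRNA regulated in several
    contrasts contributes once to the totals but once per contrast above.
    """
    linc_set = set(lincrna_ids)
    tnat_set = set(transnat_ids)
    rows = []
    seen_up: set[str] = set()
    seen_down: set[str] = set()
    seen_up_t: set[str] = set()
    seen_down_t: set[str] = set()
    for contrast, de in de_tables.items():
        sub = de[de.index.isin(linc_set)]
        up = sub[(sub["fc"] > fc_thresh) & (sub["padj"] < padj_thresh)]
        down = sub[(sub["fc"] < 1.0 / fc_thresh) & (sub["padj"] < padj_thresh)]
        up_t = up[up.index.isin(tnat_set)]
        down_t = down[down.index.isin(tnat_set)]
        seen_up |= set(up.index)
        seen_down |= set(down.index)
        seen_up_t |= set(up_t.index)
        seen_down_t |= set(down_t.index)
        rows.append(
            {
                "contrast": screens._contrast_label(contrast),
                "lincRNAs_up": len(up),
                "transNATs_up": len(up_t),
                "lincRNAs_down": len(down),
                "transNATs_down": len(down_t),
            }
        )
    rows.append(
        {
            "contrast": "unique_genes",
            "lincRNAs_up": len(seen_up),
            "transNATs_up": len(seen_up_t),
            "lincRNAs_down": len(seen_down),
            "transNATs_down": len(seen_down_t),
        }
    )
    return pd.DataFrame(rows, columns=["contrast", "lincRNAs_up", "transNATs_up", "lincRNAs_down", "transNATs_down"])
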