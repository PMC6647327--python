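"""Local-alignment engine with Karlin-Altschul E-values and the four screens.

One engine drives every homology-based screen in the package:

* antisense RNA:RNA target search (lincRNA vs reverse-complemented mRNAs),
* RNA:DNA chromatin-window search (lincRNA vs gene body + promoter windows,
  both strands),
* transposable-element content,
* miRNA-precursor (hairpin) homology.

Two alignment paths share one scoring scheme. Small problems run a full
affine-gap Smith-Waterman (anti-diagonal vectorized, exact). Large problems
run seed-and-extend: exact word matches seed candidate diagonals, and on each
seeded diagonal the optimal *ungapped* local segment is found exactly by a
maximum-subarray sweep over the whole diagonal. The seeded path reports no
gapped alignments; planted and biological near-duplexes at the identity levels
screened here are gap-free at the resolution that matters for the E<1 /
length>=100 filter.

E-values follow the ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S)
with lambda solved from the scoring scheme at uniform base composition and K
configurable (no finite-size edge correction; the search space is query length
times total database length).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .catalog import TranscriptRecord
from .io import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
NEG = -1e9


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().encode().translate(bytes(_CODE.get(chr(c), 4) for c in range(256))),
        dtype=np.int8,
    )


@dataclass
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul parameters.

    Defaults are the classic nucleotide-BLAST scheme (+2/-3, gap open 5,
    extend 2; a gap of length g costs open + g*extend). ``lam`` is solved from
    sum_ij p_i p_j exp(lam*s_ij) = 1 at uniform composition when not given;
    ``K`` defaults to 0.41.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float | None = None
    K: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam is None:
            m, x = float(self.match), float(self.mismatch)
            f = lambda l: 0.25 * math.exp(l * m) + 0.75 * math.exp(l * x) - 1.0
            self.lam = float(brentq(f, 1e-3, 10.0))

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)

    def min_score_for_evalue(self, max_e: float, m: int, n: int) -> int:
        """Smallest integer score whose E-value is below ``max_e``."""
        if m <= 0 or n <= 0:
            return 1
        s = math.log(self.K * m * n / max_e) / self.lam
        return max(int(math.floor(s)) + 1, 1)


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]  # 0-based half-open on the query
    subject_interval: tuple[int, int]  # 0-based half-open on the subject
    orientation: str = "sense"  # sense | antisense
    aln_length: int = 0
    n_mismatch: int = 0
    n_gaps: int = 0  # gap openings
    percent_identity: float = 0.0
    score: int = 0
    evalue: float = math.inf
    in_promoter: bool | None = None
    in_gene_body: bool | None = None


# ---------------------------------------------------------------------------
# Full dynamic programming (exact Smith-Waterman, affine gaps)


def _sw_matrices(qe: np.ndarray, se: np.ndarray, scheme: ScoringScheme):
    """Fill H/E/F for local alignment by anti-diagonal vectorized sweeps.

    Matrices are stored in skewed coordinates ``M[i, i + j]`` so each
    anti-diagonal update is a handful of contiguous-slice operations. All
    scores are integers stored in float32 (exact below 2**24), so traceback
    can use exact equality.
    """
    m, n = len(qe), len(se)
    width = m + n + 1
    H = np.zeros((m + 1, width), dtype=np.float32)
    E = np.full((m + 1, width), NEG, dtype=np.float32)
    F = np.full((m + 1, width), NEG, dtype=np.float32)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    ma, mi = float(scheme.match), float(scheme.mismatch)
    qf = qe.astype(np.float32)
    sf = se.astype(np.float32)
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        if lo > hi:
            continue
        q_slice = qf[lo - 1 : hi]  # bases for i = lo..hi
        s_slice = sf[d - hi - 1 : d - lo][::-1]  # bases for j = d - i
        sub = np.where((q_slice == s_slice) & (q_slice != 4), ma, mi)
        e = np.maximum(E[lo : hi + 1, d - 1], H[lo : hi + 1, d - 1] - go) - ge
        f = np.maximum(F[lo - 1 : hi, d - 1], H[lo - 1 : hi, d - 1] - go) - ge
        h = np.maximum.reduce([H[lo - 1 : hi, d - 2] + sub, e, f])
        np.maximum(h, 0.0, out=h)
        E[lo : hi + 1, d] = e
        F[lo : hi + 1, d] = f
        H[lo : hi + 1, d] = h
    return H, E, F


def _traceback(qe, se, H, E, F, i, j, scheme: ScoringScheme, used_q=None, used_s=None):
    """Walk one optimal local alignment back from cell (i, j).

    Matrices are in the skewed layout of :func:`_sw_matrices` (value of cell
    (i, j) at ``M[i, i + j]``). Returns None as soon as the walk enters a
    cell already claimed by an accepted hit (``used_q``/``used_s`` masks over
    0-based sequence positions), which keeps rejection of shadow candidates
    cheap.
    """
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    ma, mi = float(scheme.match), float(scheme.mismatch)
    n_match = n_mismatch = n_gap_cols = n_gap_open = 0
    qi_end, sj_end = i, j
    state = "H"
    while i > 0 and j > 0:
        if used_q is not None and used_q[i - 1] and used_s[j - 1]:
            return None
        if state == "H":
            if H[i, i + j] == 0:
                break
            sub = ma if (qe[i - 1] == se[j - 1] and qe[i - 1] != 4) else mi
            if H[i, i + j] == H[i - 1, i + j - 2] + sub:
                if sub == ma:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif H[i, i + j] == E[i, i + j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consumes subject
            n_gap_cols += 1
            opened = E[i, i + j] + ge != E[i, i + j - 1]
            j -= 1
            if opened:
                n_gap_open += 1
                state = "H"
        else:  # F: gap in subject, consumes query
            n_gap_cols += 1
            opened = F[i, i + j] + ge != F[i - 1, i + j - 1]
            i -= 1
            if opened:
                n_gap_open += 1
                state = "H"
    aln_length = n_match + n_mismatch + n_gap_cols
    return {
        "q_interval": (i, qi_end),
        "s_interval": (j, sj_end),
        "n_match": n_match,
        "n_mismatch": n_mismatch,
        "n_gaps": n_gap_open,
        "aln_length": aln_length,
    }


def _dp_align(query, subject, scheme, min_score, max_hits) -> list[dict]:
    qe, se = _encode(query), _encode(subject)
    m, n = len(qe), len(se)
    H, E, F = _sw_matrices(qe, se, scheme)
    hits: list[dict] = []
    if max_hits == 1:
        i, d = np.unravel_index(int(np.argmax(H)), H.shape)
        i, d = int(i), int(d)
        if H[i, d] < min_score:
            return []
        tb = _traceback(qe, se, H, E, F, i, d - i, scheme)
        tb["score"] = int(H[i, d])
        return [tb]
    candidates = np.argwhere(H >= min_score)
    order = np.argsort(H[candidates[:, 0], candidates[:, 1]], kind="stable")[::-1]
    used_q = np.zeros(m, dtype=bool)
    used_s = np.zeros(n, dtype=bool)
    # Greedy enumeration of further locally optimal alignments: candidates in
    # the score shadow of an accepted hit are rejected by an early-abort
    # traceback; the attempt budget bounds worst-case work on long shadows.
    attempts = 200 * max_hits
    for k in order:
        if len(hits) >= max_hits or attempts <= 0:
            break
        attempts -= 1
        i, d = int(candidates[k, 0]), int(candidates[k, 1])
        j = d - i
        if not (1 <= j <= n):
            continue
        if used_q[i - 1] and used_s[j - 1]:
            continue
        tb = _traceback(qe, se, H, E, F, i, j, scheme, used_q, used_s)
        if tb is None:
            continue
        qa, qb = tb["q_interval"]
        sa, sb = tb["s_interval"]
        if used_q[qa:qb].any() or used_s[sa:sb].any():
            continue
        tb["score"] = int(H[i, d])
        hits.append(tb)
        used_q[qa:qb] = True
        used_s[sa:sb] = True
    return hits


# ---------------------------------------------------------------------------
# Seed-and-extend (exact optimal ungapped segment per seeded diagonal)


class SeedIndex:
    """Exact word index over one subject sequence (words with N skipped)."""

    def __init__(self, subject: str, word_size: int = 9):
        self.word_size = word_size
        self.subject = subject.upper()
        self.encoded = _encode(subject)
        self.words: dict[str, list[int]] = {}
        w = word_size
        s = self.subject
        for pos in range(0, len(s) - w + 1):
            word = s[pos : pos + w]
            if "N" in word:
                continue
            self.words.setdefault(word, []).append(pos)

    def seeded_diagonals(self, query: str) -> set[int]:
        w = self.word_size
        q = query.upper()
        diags: set[int] = set()
        for qpos in range(0, len(q) - w + 1):
            positions = self.words.get(q[qpos : qpos + w])
            if positions:
                for spos in positions:
                    diags.add(qpos - spos)
        return diags


def _best_ungapped_on_diagonal(qe, se, d, scheme) -> dict | None:
    """Optimal local ungapped segment on diagonal d (query pos - subject pos).

    Maximum-subarray (Kadane) over the match/mismatch score series of the full
    overlap strip: exact for ungapped alignments, independent of seed length.
    """
    m, n = len(qe), len(se)
    q_lo = max(0, d)
    q_hi = min(m, n + d)
    if q_hi - q_lo < 1:
        return None
    a = qe[q_lo:q_hi]
    b = se[q_lo - d : q_hi - d]
    match = (a == b) & (a != 4)
    scores = np.where(match, float(scheme.match), float(scheme.mismatch))
    cs = np.concatenate(([0.0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - run_min
    end = int(np.argmax(gains))
    score = float(gains[end])
    if score <= 0:
        return None
    start = int(np.argmin(cs[: end + 1]))
    seg_match = int(match[start : end + 1].sum())
    length = end + 1 - start
    return {
        "q_interval": (q_lo + start, q_lo + end + 1),
        "s_interval": (q_lo + start - d, q_lo + end + 1 - d),
        "n_match": seg_match,
        "n_mismatch": length - seg_match,
        "n_gaps": 0,
        "aln_length": length,
        "score": int(score),
    }


def _seed_align(query, subject, scheme, min_score, max_hits, word_size, index=None) -> list[dict]:
    if index is None:
        index = SeedIndex(subject, word_size)
    qe = _encode(query)
    se = index.encoded
    hits = []
    for d in sorted(index.seeded_diagonals(query)):
        seg = _best_ungapped_on_diagonal(qe, se, d, scheme)
        if seg is not None and seg["score"] >= min_score:
            hits.append(seg)
    hits.sort(key=lambda h: (-h["score"], h["q_interval"]))
    return hits[:max_hits]


# ---------------------------------------------------------------------------
# Public alignment entry point


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    min_score: int = 15,
    search_space: tuple[int, int] | None = None,
    method: str = "auto",
    dp_max_cells: int = 2_000_000,
    word_size: int = 9,
    max_hits: int = 10,
    orientation: str = "sense",
    _index: SeedIndex | None = None,
) -> list[AlignmentHit]:
    """Locally align ``query`` against ``subject``; hits sorted by score.

    ``method`` is ``"dp"`` (exact Smith-Waterman), ``"seed"`` (word-seeded
    ungapped diagonals) or ``"auto"`` (DP when the matrix fits in
    ``dp_max_cells`` cells). E-values use ``search_space`` (query letters,
    database letters), defaulting to the two sequence lengths. Sequences are
    over ACGTN; N never matches.
    """
    scheme = scheme or ScoringScheme()
    if not query or not subject:
        return []
    if method == "auto":
        method = "dp" if len(query) * len(subject) <= dp_max_cells else "seed"
    if method == "dp":
        raw = _dp_align(query, subject, scheme, min_score, max_hits)
    elif method == "seed":
        raw = _seed_align(query, subject, scheme, min_score, max_hits, word_size, _index)
    else:
        raise ValueError(f"unknown method {method!r}")
    m, n = search_space if search_space is not None else (len(query), len(subject))
    hits = []
    for seg in raw:
        matches = seg["n_match"] if "n_match" in seg else seg["aln_length"] - seg["n_mismatch"]
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                query_interval=seg["q_interval"],
                subject_interval=seg["s_interval"],
                orientation=orientation,
                aln_length=seg["aln_length"],
                n_mismatch=seg["n_mismatch"],
                n_gaps=seg["n_gaps"],
                percent_identity=100.0 * matches / seg["aln_length"] if seg["aln_length"] else 0.0,
                score=seg["score"],
                evalue=scheme.evalue(seg["score"], m, n),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.query_interval, h.subject_interval))
    return hits


# ---------------------------------------------------------------------------
# Screens


def _filter(hits: list[AlignmentHit], min_len: int, max_e: float) -> list[AlignmentHit]:
    # min_len inclusive (>=), E-value strict (<)
    return [h for h in hits if h.aln_length >= min_len and h.evalue < max_e]


def scan_trans_nat(
    lincrnas: list[TranscriptRecord],
    mrnas: list[TranscriptRecord],
    scheme: ScoringScheme | None = None,
    min_len: int = 100,
    max_e: float = 1.0,
    word_size: int = 9,
) -> list[AlignmentHit]:
    """Antisense complementarity screen: lincRNAs vs reverse-complement mRNAs.

    Each lincRNA is aligned (strand-specifically) against a database of
    reverse-complemented protein-coding mRNAs; hits passing both the E-value
    and length thresholds are reported as antisense, with subject intervals
    mapped back to mRNA coordinates.
    """
    scheme = scheme or ScoringScheme()
    db = [(t.id, revcomp(_seq(t)), len(_seq(t))) for t in mrnas]
    total_n = sum(length for _, _, length in db)
    indexes = [SeedIndex(rc, word_size) for _, rc, _ in db]
    out: list[AlignmentHit] = []
    for linc in lincrnas:
        q = _seq(linc)
        floor = scheme.min_score_for_evalue(max_e, len(q), total_n)
        for (mid, rc, mlen), idx in zip(db, indexes):
            hits = local_align(
                q,
                rc,
                scheme,
                query_id=linc.id,
                subject_id=mid,
                min_score=floor,
                search_space=(len(q), total_n),
                method="seed",
                word_size=word_size,
                orientation="antisense",
                _index=idx,
            )
            for h in _filter(hits, min_len, max_e):
                a, b = h.subject_interval
                h.subject_interval = (mlen - b, mlen - a)  # back to mRNA coordinates
                out.append(h)
    out.sort(key=lambda h: (h.query_id, h.subject_id, -h.score))
    return out


def scan_dna_targets(
    lincrnas: list[TranscriptRecord],
    genes: list[TranscriptRecord],
    genome: dict[str, str],
    scheme: ScoringScheme | None = None,
    promoter_len: int = 2000,
    min_len: int = 100,
    max_e: float = 1.0,
    word_size: int = 9,
) -> list[AlignmentHit]:
    """Chromatin-window screen: lincRNAs vs gene body + promoter, both strands.

    The subject window spans the gene body plus ``promoter_len`` nt upstream of
    the annotated TSS (upstream on the gene's strand, truncated at chromosome
    edges). Hits on either strand are retained; subject intervals are genomic
    (forward-strand) coordinates, and each hit is annotated for promoter and/or
    gene-body overlap.
    """
    scheme = scheme or ScoringScheme()
    windows = []
    for g in genes:
        if g.strand not in "+-":
            warnings.warn(f"gene {g.id} has no strand; skipped in DNA-target scan")
            continue
        chrom_len = len(genome[g.chromosome])
        if g.strand == "+":
            w0, w1 = max(0, g.start - promoter_len), g.end
            prom = (w0, g.start)
        else:
            w0, w1 = g.start, min(chrom_len, g.end + promoter_len)
            prom = (g.end, w1)
        seq = genome[g.chromosome][w0:w1]
        windows.append((g, w0, w1, prom, seq))
    total_n = 2 * sum(len(seq) for *_, seq in windows)
    prepared = [
        (g, w0, w1, prom, ori, s, SeedIndex(s, word_size))
        for g, w0, w1, prom, seq in windows
        for ori, s in (("sense", seq), ("antisense", revcomp(seq)))
    ]
    out: list[AlignmentHit] = []
    for linc in lincrnas:
        q = _seq(linc)
        floor = scheme.min_score_for_evalue(max_e, len(q), total_n)
        for g, w0, w1, prom, ori, s, idx in prepared:
            hits = local_align(
                q,
                s,
                scheme,
                query_id=linc.id,
                subject_id=g.id,
                min_score=floor,
                search_space=(len(q), total_n),
                method="seed",
                word_size=word_size,
                orientation=ori,
                _index=idx,
            )
            for h in _filter(hits, min_len, max_e):
                a, b = h.subject_interval
                if ori == "sense":
                    ga, gb = w0 + a, w0 + b
                else:
                    ga, gb = w1 - b, w1 - a
                h.subject_interval = (ga, gb)
                h.in_promoter = max(ga, prom[0]) < min(gb, prom[1])
                h.in_gene_body = max(ga, g.start) < min(gb, g.end)
                out.append(h)
    out.sort(key=lambda h: (h.query_id, h.subject_id, -h.score))
    return out


def scan_library(
    lincrnas: list[TranscriptRecord],
    library: dict[str, str],
    scheme: ScoringScheme | None = None,
    max_e: float = 1e-4,
    min_len: int = 50,
    word_size: int = 9,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Generic sequence-library screen (TE content, miRNA hairpins).

    Used with (1e-12, 50) for transposable-element libraries and a looser
    E-value for hairpin homology. The best hit per (lincRNA, element) pair is
    retained.
    """
    scheme = scheme or ScoringScheme()
    if not library:
        raise ValueError("empty sequence library")
    total_n = sum(len(s) for s in library.values()) * (2 if both_strands else 1)
    prepared = []
    for eid, seq in library.items():
        prepared.append((eid, "sense", seq, SeedIndex(seq, word_size)))
        if both_strands:
            rc = revcomp(seq)
            prepared.append((eid, "antisense", rc, SeedIndex(rc, word_size)))
    best: dict[tuple[str, str], AlignmentHit] = {}
    for linc in lincrnas:
        q = _seq(linc)
        floor = scheme.min_score_for_evalue(max_e, len(q), total_n)
        for eid, ori, s, idx in prepared:
            hits = local_align(
                q,
                s,
                scheme,
                query_id=linc.id,
                subject_id=eid,
                min_score=floor,
                search_space=(len(q), total_n),
                method="seed",
                word_size=word_size,
                orientation=ori,
                _index=idx,
            )
            for h in _filter(hits, min_len, max_e):
                key = (linc.id, eid)
                if key not in best or h.score > best[key].score:
                    best[key] = h
    return sorted(best.values(), key=lambda h: (h.query_id, h.subject_id))


def _seq(t: TranscriptRecord) -> str:
    if t.sequence is None:
        raise ValueError(f"transcript {t.id} has no sequence attached")
    return t.sequence


def hits_to_frame(hits: list[AlignmentHit]):
    """BLAST outfmt-6-like table (1-based inclusive hit coordinates)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.percent_identity, 2),
                "length": h.aln_length,
                "mismatch": h.n_mismatch,
                "gapopen": h.n_gaps,
                "qstart": h.query_interval[0] + 1,
                "qend": h.query_interval[1],
                "sstart": h.subject_interval[0] + 1,
                "send": h.subject_interval[1],
                "evalue": h.evalue,
                "bitscore": h.score,
                "orientation": h.orientation,
                "in_promoter": h.in_promoter,
                "in_gene_body": h.in_gene_body,
            }
        )
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        "orientation", "in_promoter", "in_gene_body",
    ]
    return pd.DataFrame(rows, columns=cols)
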