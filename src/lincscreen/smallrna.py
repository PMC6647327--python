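"""Small-RNA coverage of transcripts and siRNA-precursor calls.

Reads of 18-28 nt are placed on transcripts by exact full-length matching
(either strand); the placement count, not genome-wide multi-mapping, is what
the statistic consumes. For each transcript carrying duplex-complementary
intervals (from the antisense screen), read density is computed inside and
outside the union of those intervals, and the enrichment score is their
ratio. A transcript is called an siRNA precursor when at least 5 unique read
sequences map inside the complementary region and the enrichment is at least
2-fold.

A read is attributed to a region by its start position (configurable to the
read midpoint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import TranscriptRecord
from .io import revcomp


@dataclass
class SmallRNAProfile:
    """Per-position read-start coverage of one transcript."""

    transcript_id: str
    length: int
    start_counts: np.ndarray
    placements: list[tuple[int, str]] = field(default_factory=list)  # (start, read seq)
    comp_intervals: list[tuple[int, int]] = field(default_factory=list)
    reads_in_comp: int | None = None
    unique_reads_in_comp: int | None = None
    density_comp: float | None = None
    density_noncomp: float | None = None
    enrichment: float | None = None

    @property
    def total_mapped(self) -> int:
        return len(self.placements)


@dataclass
class PrecursorCall:
    transcript_id: str
    is_precursor: bool
    unique_reads_ok: bool
    enrichment_ok: bool


def _merge_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    clipped = sorted(
        (max(0, a), min(length, b)) for a, b in intervals if min(length, b) > max(0, a)
    )
    merged: list[tuple[int, int]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def map_small_reads(
    reads: list[tuple[str, str]],
    transcripts: list[TranscriptRecord],
    min_len: int = 18,
    max_len: int = 28,
) -> dict[str, SmallRNAProfile]:
    """Exact full-length placement of small reads on transcript sequences.

    Reads outside the [min_len, max_len] band are discarded. A read (or its
    reverse complement) occurring at several positions contributes a count at
    every matching start position.
    """
    profiles = {
        t.id: SmallRNAProfile(
            transcript_id=t.id,
            length=len(t.sequence or ""),
            start_counts=np.zeros(len(t.sequence or ""), dtype=np.int64),
        )
        for t in transcripts
    }
    kept: dict[str, int] = {}
    for _, seq in reads:
        if min_len <= len(seq) <= max_len:
            kept[seq] = kept.get(seq, 0) + 1
    for t in transcripts:
        subject = t.sequence or ""
        prof = profiles[t.id]
        for seq, copies in kept.items():
            for probe in {seq, revcomp(seq)}:
                start = subject.find(probe)
                while start != -1:
                    prof.start_counts[start] += copies
                    prof.placements.extend([(start, seq)] * copies)
                    start = subject.find(probe, start + 1)
    for prof in profiles.values():
        prof.placements.sort()
    return profiles


def score_profile(
    profile: SmallRNAProfile,
    comp_intervals: list[tuple[int, int]],
    min_unique: int = 5,
    min_enrichment: float = 2.0,
    use_midpoint: bool = False,
) -> tuple[SmallRNAProfile, PrecursorCall]:
    """Complete a profile with densities over complementary regions and call it.

    Overlapping complementary intervals are unioned first. The enrichment is
    density_comp / density_noncomp; it is infinite when only the complementary
    region carries reads and undefined (None) when neither region does, or
    when the complementary region covers the whole transcript.
    """
    merged = _merge_intervals(comp_intervals, profile.length)
    comp_len = sum(b - a for a, b in merged)
    noncomp_len = profile.length - comp_len
    profile.comp_intervals = merged

    def _pos(start: int, seq: str) -> int:
        return start + len(seq) // 2 if use_midpoint else start

    in_comp = [
        (start, seq)
        for start, seq in profile.placements
        if any(a <= _pos(start, seq) < b for a, b in merged)
    ]
    n_comp = len(in_comp)
    n_noncomp = profile.total_mapped - n_comp
    profile.reads_in_comp = n_comp
    profile.unique_reads_in_comp = len({seq for _, seq in in_comp})
    profile.density_comp = n_comp / comp_len if comp_len else None
    profile.density_noncomp = n_noncomp / noncomp_len if noncomp_len else None

    if noncomp_len == 0:
        if comp_len:
            warnings.warn(
                f"{profile.transcript_id}: complementary region covers the whole transcript; "
                "enrichment undefined"
            )
        profile.enrichment = None
    elif profile.density_noncomp == 0:
        profile.enrichment = math.inf if n_comp > 0 else None
    elif comp_len == 0:
        profile.enrichment = None
    else:
        profile.enrichment = profile.density_comp / profile.density_noncomp

    unique_ok = (profile.unique_reads_in_comp or 0) >= min_unique
    enrich_ok = profile.enrichment is not None and profile.enrichment >= min_enrichment
    call = PrecursorCall(
        transcript_id=profile.transcript_id,
        is_precursor=unique_ok and enrich_ok,
        unique_reads_ok=unique_ok,
        enrichment_ok=enrich_ok,
    )
    return profile, call
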