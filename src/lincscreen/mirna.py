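"""miRNA target-mimic detection and simplified binding-site scoring.

A target mimic sequesters a miRNA by pairing it almost perfectly while
bulging out the cleavage site, so the duplex forms but cannot be sliced (the
IPS1/miR399 configuration). The detector applies the classical mimic rules:

1. perfect Watson-Crick pairing to miRNA positions 2-8 (the seed),
2. a bulge on the target strand, opposite miRNA positions 9-12 only,
3. the bulge is exactly three nucleotides, and at most three mismatches or
   G:U pairs over the remaining paired positions (the bulge not counted).

Positions count from the miRNA 5' end. The default convention places the
3-nt target-side bulge between miRNA pairing positions 9 and 12; the
alternative 3'-counted convention is available behind a switch.

Binding sites (cleavage-competent pairing) are scored with the classical
plant-target penalty scheme: mismatch 1, G:U 0.5, gap 2, doubled within
miRNA positions 2-13; windows at or below the expectation threshold are
reported. The search is ungapped; unpaired-energy filtering is not evaluated
and sites carry ``upe_not_evaluated=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pair_class(mirna_base: str, target_base: str) -> str:
    """WC, GU or mismatch for one miRNA:target base pair."""
    m, t = _norm(mirna_base), _norm(target_base)
    if _COMP.get(m) == t and m != "N":
        return "WC"
    if (m == "G" and t == "T") or (m == "T" and t == "G"):
        return "GU"
    return "mismatch"


@dataclass
class MimicCall:
    lincrna_id: str
    mirna_id: str
    site_start: int  # 0-based on the lincRNA
    site_end: int
    bulge_interval: tuple[int, int]  # lincRNA-side, length 3
    bulge_after_position: int  # miRNA position preceding the bulge insertion
    n_mismatch_plus_gu: int
    paired_map: list[tuple[int, int, str]] = field(default_factory=list)  # (miRNA pos, linc pos, class)


@dataclass
class BindingSite:
    lincrna_id: str
    mirna_id: str
    site_start: int
    site_end: int
    expectation: float
    penalties: list[float] = field(default_factory=list)  # per miRNA position 1..L
    upe_not_evaluated: bool = True


def _pair_offsets(mirna_len: int, bulge_after: int, bulge_len: int = 3):
    """Site offset paired with each miRNA position for a given bulge placement.

    The site (read 5'->3' on the lincRNA) spans mirna_len + bulge_len bases;
    pairing is antiparallel. The bulge sits between the bases pairing miRNA
    positions ``bulge_after`` and ``bulge_after + 1``.
    """
    S = mirna_len + bulge_len
    offsets = {}
    for p in range(1, mirna_len + 1):
        offsets[p] = S - p if p <= bulge_after else S - bulge_len - p
    return offsets, S


def find_mimic_sites(
    linc_seq: str,
    mirna_seq: str,
    lincrna_id: str = "lincRNA",
    mirna_id: str = "miRNA",
    max_mismatch_gu: int = 3,
    bulge_len: int = 3,
    bulge_positions: tuple[int, int] = (9, 12),
    seed_range: tuple[int, int] = (2, 8),
    count_from_3prime: bool = False,
) -> list[MimicCall]:
    """All lincRNA windows satisfying the target-mimic rules.

    Every window admitting a bulged antiparallel alignment that keeps the
    seed perfectly Watson-Crick, places a 3-nt target-strand bulge opposite
    the allowed miRNA positions and accumulates at most ``max_mismatch_gu``
    mismatches or G:U pairs elsewhere is reported; overlapping placements of
    the same site collapse to the best-scoring one.
    """
    linc = _norm(linc_seq)
    mir = _norm(mirna_seq)
    L = len(mir)
    if not (19 <= L <= 24):
        raise ValueError("mature miRNA length expected in 19-24 nt")
    lo, hi = bulge_positions
    if count_from_3prime:
        lo, hi = L + 1 - hi, L + 1 - lo
    arr = np.frombuffer(linc.encode(), dtype="S1")
    n = len(linc)
    calls: list[MimicCall] = []
    # The bulge between pairing positions b and b+1 must sit opposite
    # miRNA positions lo..hi, i.e. lo <= b <= hi - 1.
    for b in range(lo, hi):
        offsets, S = _pair_offsets(L, b, bulge_len)
        n_windows = n - S + 1
        if n_windows <= 0:
            continue
        wc = np.ones(n_windows, dtype=bool)
        badness = np.zeros(n_windows, dtype=np.int16)
        for p in range(1, L + 1):
            o = offsets[p]
            window_bases = arr[o : o + n_windows]
            is_wc = window_bases == _COMP[mir[p - 1]].encode()
            if seed_range[0] <= p <= seed_range[1]:
                wc &= is_wc
            badness += (~is_wc).astype(np.int16)
        ok = wc & (badness <= max_mismatch_gu)
        for i in np.nonzero(ok)[0]:
            i = int(i)
            paired = [
                (p, i + offsets[p], pair_class(mir[p - 1], linc[i + offsets[p]]))
                for p in range(1, L + 1)
            ]
            bulge_lo = i + offsets[b + 1] + 1
            calls.append(
                MimicCall(
                    lincrna_id=lincrna_id,
                    mirna_id=mirna_id,
                    site_start=i,
                    site_end=i + S,
                    bulge_interval=(bulge_lo, bulge_lo + bulge_len),
                    bulge_after_position=b,
                    n_mismatch_plus_gu=int(badness[i]),
                    paired_map=paired,
                )
            )
    # collapse overlapping placements of one physical site
    calls.sort(key=lambda c: (c.n_mismatch_plus_gu, c.bulge_after_position, c.site_start))
    kept: list[MimicCall] = []
    for call in calls:
        if any(max(call.site_start, k.site_start) < min(call.site_end, k.site_end) for k in kept):
            continue
        kept.append(call)
    kept.sort(key=lambda c: c.site_start)
    return kept


# ---------------------------------------------------------------------------
# binding sites


def find_binding_sites(
    linc_seq: str,
    mirna_seq: str,
    lincrna_id: str = "lincRNA",
    mirna_id: str = "miRNA",
    expectation_max: float = 3.0,
    mismatch_penalty: float = 1.0,
    gu_penalty: float = 0.5,
    core_range: tuple[int, int] = (2, 13),
    core_multiplier: float = 2.0,
) -> list[BindingSite]:
    """Ungapped sliding-window miRNA binding-site scan.

    Each window of miRNA length is scored by summed per-position penalties
    (antiparallel pairing); windows with expectation <= ``expectation_max``
    are reported, best first.
    """
    linc = _norm(linc_seq)
    mir = _norm(mirna_seq)
    L = len(mir)
    n_windows = len(linc) - L + 1
    if n_windows <= 0:
        return []
    arr = np.frombuffer(linc.encode(), dtype="S1")
    total = np.zeros(n_windows, dtype=float)
    per_pos = np.zeros((L, n_windows), dtype=float)
    for p in range(1, L + 1):
        o = L - p  # antiparallel: miRNA position p pairs window offset L - p
        window_bases = arr[o : o + n_windows]
        comp = _COMP[mir[p - 1]].encode()
        is_wc = window_bases == comp
        if mir[p - 1] == "G":
            is_gu = window_bases == b"T"
        elif mir[p - 1] == "T":
            is_gu = window_bases == b"G"
        else:
            is_gu = np.zeros(n_windows, dtype=bool)
        pen = np.where(is_wc, 0.0, np.where(is_gu, gu_penalty, mismatch_penalty))
        if core_range[0] <= p <= core_range[1]:
            pen = pen * core_multiplier
        per_pos[p - 1] = pen
        total += pen
    sites = [
        BindingSite(
            lincrna_id=lincrna_id,
            mirna_id=mirna_id,
            site_start=int(i),
            site_end=int(i) + L,
            expectation=float(total[i]),
            penalties=[float(per_pos[p, i]) for p in range(L)],
        )
        for i in np.nonzero(total <= expectation_max)[0]
    ]
    sites.sort(key=lambda s: (s.expectation, s.site_start))
    return sites
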