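"""Plain-text format helpers: FASTA, bedGraph, TSV.

GTF reading/writing lives in :mod:`lincscreen.catalog` next to the transcript
model it populates.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T, N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastx_reads(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read small-RNA reads from FASTA or FASTQ (sniffed from the first byte)."""
    from Bio import SeqIO

    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper().replace("U", "T")) for rec in SeqIO.parse(str(path), fmt)]


def read_bedgraph(path: str | os.PathLike) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph track into ``{chrom: (starts, ends, scores)}`` arrays.

    Coordinates are kept 0-based half-open as in the format. Intervals are
    sorted per chromosome; overlaps are not resolved (bedGraph forbids them).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        out[str(chrom)] = (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
            sub["score"].to_numpy(dtype=float),
        )
    return out


def write_bedgraph(intervals: list[tuple[str, int, int, float]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.4f}\n")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
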