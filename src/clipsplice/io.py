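"""Flat-file readers and writers (BED6, peak BED6+3, FASTA, GTF)."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLS,
        comment="#",
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


def write_bed6(df: pd.DataFrame, path: str) -> None:
    df[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_peaks_bed(peaks: Iterable, path: str) -> None:
    """BED6+3: name=peak id, score=height, extras summit, fdr, support count."""
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            [p.chrom, p.start, p.end, p.name or f"peak_{i}", p.height, p.strand,
             p.summit, f"{p.fdr:.6g}", len(p.support)]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str):
    from .peaks import Peak

    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                    height=int(f[4]), strand=f[5], summit=int(f[6]),
                    fdr=float(f[7]), support=tuple(range(int(f[8]))),
                )
            )
    return peaks


def write_fasta(records: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
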