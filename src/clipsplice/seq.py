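"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def fetch(fasta, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Strand-oriented slice from a pyfaidx.Fasta (clipped at contig ends)."""
    start = max(0, start)
    end = min(len(fasta[chrom]), end)
    if end <= start:
        return ""
    s = str(fasta[chrom][start:end])
    return revcomp(s) if strand == "-" else s
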