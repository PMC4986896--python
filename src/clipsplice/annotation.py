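"""Gene models, representative transcriptome and coordinate conversion.

Internal coordinates are 0-based, half-open (BED convention).  GTF input is
converted on read (1-based closed -> subtract 1 from starts).  Strand-aware
semantics: the 5' end of a feature is its genomic start on ``+`` and its
genomic end on ``-``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """One transcript: a sorted list of disjoint exon intervals plus optional CDS."""

    transcript_id: str
    exons: list[Interval]
    cds_start: Optional[int] = None  # genomic, half-open with cds_end
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon ({a},{b})")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def cds_length(self) -> int:
        """Summed exonic overlap with the CDS interval (0 when no CDS)."""
        if self.cds_start is None or self.cds_end is None:
            return 0
        return sum(
            max(0, min(b, self.cds_end) - max(a, self.cds_start))
            for a, b in self.exons
        )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def span(self) -> Interval:
        a = min(t.span[0] for t in self.transcripts)
        b = max(t.span[1] for t in self.transcripts)
        return a, b


@dataclass
class IntronInterval:
    intron_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str = ""
    upstream_exon: str = ""  # exon on the 5' side, transcription orientation
    downstream_exon: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def select_representative(genes: Iterable[GeneModel]) -> dict[str, TranscriptModel]:
    """Pick one transcript per gene: maximal CDS length.

    Ties broken by longer spliced length then lexicographically smallest
    transcript id.  Genes with no CDS anywhere fall back to the longest
    spliced transcript (same tie-break).
    """
    out: dict[str, TranscriptModel] = {}
    for gene in genes:
        if not gene.transcripts:
            raise ValueError(f"gene {gene.gene_id} has no transcripts")
        out[gene.gene_id] = min(
            gene.transcripts,
            key=lambda t: (-t.cds_length, -t.spliced_length, t.transcript_id),
        )
    return out


def derive_introns(
    transcript: TranscriptModel,
    chrom: str = "",
    strand: str = "+",
    gene_id: str = "",
) -> list[IntronInterval]:
    """Introns exactly tiling the gaps between consecutive exons.

    n exons -> n-1 introns; single-exon transcripts yield an empty list.
    Intron numbering follows transcription order (intron 1 is 5'-most).
    """
    if not transcript.exons:
        raise ValueError("transcript has no exons")
    gaps = []
    for (_, b1), (a2, _) in zip(transcript.exons, transcript.exons[1:]):
        if a2 <= b1:
            raise ValueError(f"{transcript.transcript_id}: exons overlap or abut")
        gaps.append((b1, a2))
    n = len(gaps)
    introns = []
    for i, (a, b) in enumerate(gaps):
        # genomic order; transcription order index depends on strand
        k = i if strand == "+" else n - 1 - i
        introns.append(
            IntronInterval(
                intron_id=f"{transcript.transcript_id}.i{k + 1}",
                chrom=chrom,
                strand=strand,
                start=a,
                end=b,
                gene_id=gene_id,
                upstream_exon=f"{transcript.transcript_id}.e{k + 1}",
                downstream_exon=f"{transcript.transcript_id}.e{k + 2}",
            )
        )
    if strand == "-":
        introns.sort(key=lambda x: x.start)
    return introns


def genomic_to_transcriptomic(
    pos: int, transcript: TranscriptModel, strand: str
) -> Optional[int]:
    """0-based offset from the transcript 5' end; ``None`` for intronic positions."""
    off = 0
    plus = None
    for a, b in transcript.exons:
        if a <= pos < b:
            plus = off + (pos - a)
            break
        off += b - a
    if plus is None:
        return None
    if strand == "+":
        return plus
    return transcript.spliced_length - 1 - plus


def transcriptomic_to_genomic(
    offset: int, transcript: TranscriptModel, strand: str
) -> int:
    """Inverse of :func:`genomic_to_transcriptomic`; hard error outside range."""
    n = transcript.spliced_length
    if not 0 <= offset < n:
        raise ValueError(f"offset {offset} outside [0, {n})")
    plus = offset if strand == "+" else n - 1 - offset
    for a, b in transcript.exons:
        w = b - a
        if plus < w:
            return a + plus
        plus -= w
    raise AssertionError("unreachable")


def exon_boundaries_transcriptomic(transcript: TranscriptModel, strand: str) -> list[Interval]:
    """Exon intervals in transcript coordinates, 5'->3' order."""
    lens = [b - a for a, b in transcript.exons]
    if strand == "-":
        lens = lens[::-1]
    out, off = [], 0
    for w in lens:
        out.append((off, off + w))
        off += w
    return out


class GeneIndex:
    """Sorted per-(chrom, strand) gene span index for point queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for i, g in enumerate(self.genes):
            a, b = g.span
            self._by_key.setdefault((g.chrom, g.strand), []).append((a, b, i))
        for v in self._by_key.values():
            v.sort()

    def at(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        rows = self._by_key.get((chrom, strand), [])
        hi = bisect.bisect_right(rows, (pos, float("inf"), -1))
        hits = []
        for a, b, i in rows[:hi]:
            if a <= pos < b:
                hits.append(self.genes[i])
        return hits


# ---------------------------------------------------------------------------
# readers / writers


def read_gtf(path: str) -> list[GeneModel]:
    """Load gene models from GTF (gene_id / transcript_id attributes required)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        g = per_gene.setdefault(
            gid,
            {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (feat.attributes.get("gene_biotype") or ["protein_coding"])[0],
                "tx": {},
            },
        )
        t = g["tx"].setdefault(tid, {"exons": [], "cds": []})
        iv = (feat.start - 1, feat.end)  # GTF is 1-based closed
        t["exons" if feat.featuretype == "exon" else "cds"].append(iv)
    genes = []
    for gid in sorted(per_gene):
        g = per_gene[gid]
        txs = []
        for tid in sorted(g["tx"]):
            t = g["tx"][tid]
            cds_start = min(a for a, _ in t["cds"]) if t["cds"] else None
            cds_end = max(b for _, b in t["cds"]) if t["cds"] else None
            txs.append(TranscriptModel(tid, t["exons"], cds_start, cds_end))
        genes.append(GeneModel(gid, g["chrom"], g["strand"], txs, g["biotype"]))
    return genes


def read_bed12(path: str) -> list[GeneModel]:
    """Each BED12 row becomes a single-transcript gene (name = gene & transcript id)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            cds = (thick_s, thick_e) if thick_e > thick_s else (None, None)
            tx = TranscriptModel(name, exons, cds[0], cds[1])
            genes.append(GeneModel(name, chrom, strand, [tx]))
    return genes


def write_bed12(genes: Iterable[GeneModel], representative: dict[str, TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            t = representative[g.gene_id]
            a, b = t.span
            thick = (t.cds_start, t.cds_end) if t.cds_start is not None else (a, a)
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offs = ",".join(str(s - a) for s, _ in t.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [g.chrom, a, b, t.transcript_id, 0, g.strand,
                         thick[0], thick[1], 0, len(t.exons), sizes, offs],
                    )
                )
                + "\n"
            )


def spliced_sequence(transcript: TranscriptModel, strand: str, fetch) -> str:
    """Spliced 5'->3' sequence; ``fetch(start, end)`` returns + strand sequence."""
    from .seq import revcomp

    s = "".join(fetch(a, b) for a, b in transcript.exons)
    return revcomp(s) if strand == "-" else s


def write_transcriptome_fasta(
    genes: Iterable[GeneModel],
    representative: dict[str, TranscriptModel],
    fasta,
    path: str,
    width: int = 60,
) -> None:
    """Representative transcriptome FASTA (``fasta`` is a pyfaidx.Fasta)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            t = representative[g.gene_id]
            seq = spliced_sequence(t, g.strand, lambda a, b: str(fasta[g.chrom][a:b]))
            fh.write(f">{t.transcript_id} gene={g.gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
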