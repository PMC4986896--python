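"""Synthetic genomes, cross-link read sets and splicing count tables.

Everything is a pure function of (config, seed).  Generated truth records
are sufficient to score recall/precision of every downstream stage.

Cross-link positions are represented as single-nucleotide points (the
nucleotide 5' of the read start under the truncation convention); the peak
caller extends them before building coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    IntronInterval,
    TranscriptModel,
    derive_introns,
    genomic_to_transcriptomic,
    transcriptomic_to_genomic,
)
from .io import BED6_COLS
from .seq import revcomp

BASES = np.array(list("ACGT"))

# Donor 9-mer (3 exonic + 6 intronic) and acceptor 23-mer (20 intronic +
# 3 exonic) base probabilities, ACGT order.  GT / AG dinucleotides are fixed
# in both classes so every intron stays canonical.


def _pwm_from_consensus(consensus: str, p: float, fixed: Sequence[int]) -> np.ndarray:
    pwm = np.full((len(consensus), 4), 0.0)
    for i, b in enumerate(consensus):
        j = "ACGT".index(b)
        if i in fixed:
            pwm[i, j] = 1.0
        else:
            pwm[i] = (1 - p) / 3
            pwm[i, j] = p
    return pwm


def _weaken(pwm: np.ndarray, lam: float, fixed: Sequence[int]) -> np.ndarray:
    out = lam * pwm + (1 - lam) * 0.25
    for i in fixed:
        out[i] = pwm[i]
    return out


DONOR_FIXED = (3, 4)  # the GT
DONOR_STRONG = _pwm_from_consensus("CAGGTAAGT", 0.85, DONOR_FIXED)
DONOR_WEAK = _weaken(DONOR_STRONG, 0.45, DONOR_FIXED)

ACCEPTOR_FIXED = (18, 19)  # the AG
_acc = np.tile([0.08, 0.38, 0.08, 0.46], (23, 1))  # pyrimidine-rich run
_acc[18] = [1, 0, 0, 0]
_acc[19] = [0, 0, 1, 0]
_acc[20:] = [0.3, 0.2, 0.3, 0.2]  # mild exonic bias
ACCEPTOR_STRONG = _acc
ACCEPTOR_WEAK = _weaken(ACCEPTOR_STRONG, 0.45, ACCEPTOR_FIXED)


def sample_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=row / row.sum()) for row in pwm]
    return "".join(BASES[idx])


def random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@dataclass
class GenomeConfig:
    n_genes: int = 50
    exon_count_range: tuple[int, int] = (3, 7)  # inclusive
    exon_len_range: tuple[int, int] = (90, 280)
    intron_len_mean_optimal: float = 900.0
    intron_len_mean_suboptimal: float = 450.0
    intron_len_sigma: float = 0.25  # lognormal sigma
    min_intron_len: int = 80
    gc_exon: float = 0.5
    gc_intron_optimal: float = 0.40
    gc_intron_suboptimal: float = 0.56
    p_suboptimal: float = 0.5
    utr5_len: int = 60
    utr3_len: int = 60
    intergene_gap: int = 400
    genes_per_chrom: int = 25
    both_strands: bool = True


@dataclass
class TruthBindingSite:
    site_id: str
    gene_id: str
    chrom: str
    strand: str
    summit: int  # genomic position of the planted cross-link pile
    strength: float  # expected reads per full-depth replicate
    context: str  # exon_CDS | UTR5 | UTR3 | intron_5ss_proximal | intron_3ss | exon_minus24
    intron_id: str = ""


@dataclass
class TruthSpliceEffect:
    event_id: str
    event_type: str  # cassette | alt5 | alt3 | intron_retention
    psi_control: float  # percent (pir for intron_retention)
    delta: float  # knockdown - control, percent
    clip_status: str = ""
    intron_id: str = ""


@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    sequences: dict[str, str]
    intron_class: dict[str, str]  # intron_id -> optimal | suboptimal
    config: GenomeConfig

    @property
    def introns(self) -> dict[str, IntronInterval]:
        out = {}
        for g in self.genes:
            for iv in derive_introns(g.transcripts[0], g.chrom, g.strand, g.gene_id):
                out[iv.intron_id] = iv
        return out

    def representative(self) -> dict[str, TranscriptModel]:
        return {g.gene_id: g.transcripts[0] for g in self.genes}


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> SimulatedGenome:
    """Build a deterministic synthetic genome with two intron classes.

    'suboptimal' introns are shorter, GC-richer and carry weakened splice-site
    consensus sequences relative to the 'optimal' class.
    """
    cfg = config or GenomeConfig()
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    body_min = cfg.min_intron_len - 26  # 6 donor + 20 acceptor nt live in the intron
    if body_min < 0 or cfg.intron_len_mean_suboptimal < cfg.min_intron_len:
        raise ValueError("infeasible intron length constraints")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    intron_class: dict[str, str] = {}
    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}

    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1:04d}"
        tid = f"{gene_id}.t1"
        chrom = f"chr{gi // cfg.genes_per_chrom + 1}"
        if chrom not in chrom_parts:
            chrom_parts[chrom] = []
            chrom_cursor[chrom] = 0
        strand = "+" if not cfg.both_strands else ("+", "-")[rng.integers(2)]

        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_ex)
        classes = np.where(
            rng.random(n_ex - 1) < cfg.p_suboptimal, "suboptimal", "optimal"
        )
        mean = {
            "optimal": cfg.intron_len_mean_optimal,
            "suboptimal": cfg.intron_len_mean_suboptimal,
        }
        intron_lens = []
        for cls in classes:
            mu = np.log(mean[cls]) - cfg.intron_len_sigma**2 / 2
            L = int(round(rng.lognormal(mu, cfg.intron_len_sigma)))
            intron_lens.append(max(L, cfg.min_intron_len))

        # transcription-orientation sequence and local segment table
        parts: list[str] = []
        local_exons: list[tuple[int, int]] = []
        pos = 0
        for i in range(n_ex):
            ex = random_seq(int(exon_lens[i]), cfg.gc_exon, rng)
            if i < n_ex - 1:
                cls = classes[i]
                donor = sample_pwm(DONOR_STRONG if cls == "optimal" else DONOR_WEAK, rng)
                acceptor = sample_pwm(
                    ACCEPTOR_STRONG if cls == "optimal" else ACCEPTOR_WEAK, rng
                )
                ex = ex[:-3] + donor[:3]
                body = random_seq(
                    intron_lens[i] - 26,
                    cfg.gc_intron_optimal if cls == "optimal" else cfg.gc_intron_suboptimal,
                    rng,
                )
                intron_seq = donor[3:] + body + acceptor[:20]
            else:
                intron_seq = ""
            parts.append(ex)
            local_exons.append((pos, pos + len(ex)))
            pos += len(ex)
            if intron_seq:
                parts.append(intron_seq)
                pos += len(intron_seq)
        seq = "".join(parts)
        L = len(seq)

        g0 = chrom_cursor[chrom]
        if strand == "+":
            to_genomic = lambda a, b: (g0 + a, g0 + b)
            gseq = seq
        else:
            to_genomic = lambda a, b: (g0 + L - b, g0 + L - a)
            gseq = revcomp(seq)
        exons = sorted(to_genomic(a, b) for a, b in local_exons)

        # CDS in spliced coordinates [utr5, spliced_len - utr3)
        spliced_len = int(exon_lens.sum())
        c_lo = min(cfg.utr5_len, spliced_len // 3)
        c_hi = spliced_len - min(cfg.utr3_len, spliced_len // 3)
        tx = TranscriptModel(tid, exons)
        cds_a = transcriptomic_to_genomic(c_lo, tx, strand)
        cds_b = transcriptomic_to_genomic(c_hi - 1, tx, strand)
        tx.cds_start, tx.cds_end = min(cds_a, cds_b), max(cds_a, cds_b) + 1

        genes.append(GeneModel(gene_id, chrom, strand, [tx]))
        for j, cls in enumerate(classes):
            intron_class[f"{tid}.i{j + 1}"] = str(cls)
        chrom_parts[chrom].append(gseq)
        chrom_parts[chrom].append(random_seq(cfg.intergene_gap, 0.4, rng))
        chrom_cursor[chrom] += L + cfg.intergene_gap

    for chrom, parts in chrom_parts.items():
        sequences[chrom] = "".join(parts)
    return SimulatedGenome(genes, sequences, intron_class, cfg)


def write_genome(sim: SimulatedGenome, fasta_path: str, gtf_path: str) -> None:
    from .io import write_fasta

    write_fasta(dict(sorted(sim.sequences.items())), fasta_path)
    with open(gtf_path, "w") as fh:
        for g in sorted(sim.genes, key=lambda g: (g.chrom, g.span[0])):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            a, b = g.span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds_start is not None:
                    for s, e in t.exons:
                        cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                        if ce > cs:
                            fh.write(
                                f"{g.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{tattrs}\n"
                            )


# ---------------------------------------------------------------------------
# binding sites and iCLIP reads

SITE_CONTEXTS = (
    "exon_CDS",
    "UTR5",
    "UTR3",
    "intron_5ss_proximal",
    "intron_3ss",
    "exon_minus24",
)


def plant_binding_sites(
    sim: SimulatedGenome,
    n_sites: int,
    contexts: Sequence[str] | str = "exon_CDS",
    strength: float = 30.0,
    seed: int = 0,
    suboptimal_coupling: float = 0.0,
) -> list[TruthBindingSite]:
    """Place truth sites in the requested feature contexts.

    ``suboptimal_coupling`` is the probability that an intronic site is
    forced into a 'suboptimal'-class intron (when one is available in the
    chosen gene).
    """
    if isinstance(contexts, str):
        contexts = [contexts]
    for c in contexts:
        if c not in SITE_CONTEXTS:
            raise ValueError(f"unknown context {c!r}")
    rng = np.random.default_rng(seed)
    sites: list[TruthBindingSite] = []
    genes = sim.genes
    attempts = 0
    while len(sites) < n_sites and attempts < 50 * n_sites:
        attempts += 1
        g = genes[rng.integers(len(genes))]
        tx = g.transcripts[0]
        ctx = contexts[rng.integers(len(contexts))]
        summit: Optional[int] = None
        intron_id = ""
        if ctx in ("exon_CDS", "UTR5", "UTR3"):
            n = tx.spliced_length
            lo_off = genomic_to_transcriptomic(
                tx.cds_start if g.strand == "+" else tx.cds_end - 1, tx, g.strand
            )
            hi_off = genomic_to_transcriptomic(
                tx.cds_end - 1 if g.strand == "+" else tx.cds_start, tx, g.strand
            )
            if ctx == "exon_CDS":
                rng_lo, rng_hi = lo_off, hi_off
            elif ctx == "UTR5":
                rng_lo, rng_hi = 0, lo_off - 1
            else:
                rng_lo, rng_hi = hi_off + 1, n - 1
            if rng_hi - rng_lo < 4:
                continue
            off = int(rng.integers(rng_lo + 2, rng_hi - 1))
            summit = transcriptomic_to_genomic(off, tx, g.strand)
        elif ctx in ("intron_5ss_proximal", "intron_3ss"):
            introns = derive_introns(tx, g.chrom, g.strand, g.gene_id)
            if not introns:
                continue
            need = 140 if ctx == "intron_5ss_proximal" else 60
            cand = [iv for iv in introns if iv.length >= need]
            if not cand:
                continue
            if suboptimal_coupling > 0 and rng.random() < suboptimal_coupling:
                sub = [iv for iv in cand if sim.intron_class.get(iv.intron_id) == "suboptimal"]
                if sub:
                    cand = sub
            iv = cand[rng.integers(len(cand))]
            intron_id = iv.intron_id
            if ctx == "intron_5ss_proximal":
                d = int(rng.integers(25, 101))
                summit = iv.start + d if g.strand == "+" else iv.end - 1 - d
            else:
                d = int(rng.integers(25, 41))
                summit = iv.end - 1 - d if g.strand == "+" else iv.start + d
        else:  # exon_minus24: 24 nt upstream of an internal exon 3' end
            if len(tx.exons) < 3:
                continue
            order = tx.exons if g.strand == "+" else tx.exons[::-1]
            internal = order[1:-1]
            a, b = internal[rng.integers(len(internal))]
            summit = b - 1 - 24 if g.strand == "+" else a + 24
        if summit is None:
            continue
        sites.append(
            TruthBindingSite(
                site_id=f"site_{len(sites) + 1:04d}",
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                summit=int(summit),
                strength=float(strength),
                context=ctx,
                intron_id=intron_id,
            )
        )
    if len(sites) < n_sites:
        raise RuntimeError("could not place requested number of sites")
    return sites


def truth_sites_table(sites: Sequence[TruthBindingSite]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in sites])


def simulate_iclip(
    sim: SimulatedGenome,
    sites: Sequence[TruthBindingSite],
    background_rate: float = 0.01,
    n_replicates: int = 3,
    control: bool = False,
    seed: int = 0,
    depth_factors: Sequence[float] | None = None,
    jitter_sd: float = 2.0,
    control_site_factor: float = 0.0,
) -> list[pd.DataFrame]:
    """Cross-link point reads (BED6 frames, one per replicate).

    Per-site read counts are Poisson(strength x depth factor) with normal
    positional jitter; background is uniform over gene spans at
    ``background_rate`` reads/nt.  Controls keep the background but damp the
    sites by ``control_site_factor``.  The default replicate asymmetry puts
    one replicate at half depth to exercise consensus logic.
    """
    if depth_factors is None:
        depth_factors = [1.0] * n_replicates
        if n_replicates >= 3 and not control:
            depth_factors[-1] = 0.5
    rng = np.random.default_rng(seed)
    site_factor = control_site_factor if control else 1.0
    spans = {g.gene_id: (g.chrom, g.strand, *g.span) for g in sim.genes}
    out = []
    for r in range(n_replicates):
        f = depth_factors[r]
        rows: list[tuple] = []
        for s in sites:
            lam = s.strength * f * site_factor
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            if jitter_sd > 0:
                pos = s.summit + np.rint(rng.normal(0, jitter_sd, n)).astype(int)
            else:
                pos = np.full(n, s.summit)
            _, _, ga, gb = spans[s.gene_id]
            pos = np.clip(pos, ga, gb - 1)
            rows.extend((s.chrom, int(p), int(p) + 1, s.strand) for p in pos)
        if background_rate > 0:
            for g in sim.genes:
                a, b = g.span
                n = int(rng.poisson(background_rate * (b - a) * f))
                if n == 0:
                    continue
                pos = rng.integers(a, b, n)
                rows.extend((g.chrom, int(p), int(p) + 1, g.strand) for p in pos)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        df["name"] = [f"r{r}_{i}" for i in range(len(df))]
        df["score"] = 1
        df = df[BED6_COLS].sort_values(["chrom", "start", "strand"], kind="stable")
        out.append(df.reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# splicing events and count tables


def plant_splice_effects(
    sim: SimulatedGenome,
    n_cassette: int = 0,
    n_ir: int = 0,
    delta_choices: Sequence[float] = (0.0,),
    seed: int = 0,
    psi_range: tuple[float, float] = (30.0, 70.0),
    pir_range: tuple[float, float] = (2.0, 20.0),
    ir_intron_ids: Sequence[str] | None = None,
    ir_deltas: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, list[TruthSpliceEffect]]:
    """Pick cassette exons / retained introns and attach true psi/pir + delta.

    ``ir_intron_ids``/``ir_deltas`` pin IR events to specific introns with
    specific effect sizes (used to couple retention changes to CLIP status).
    Returns (event coordinate table, truth effects).
    """
    rng = np.random.default_rng(seed)
    introns_by_id = sim.introns
    rows, truths = [], []

    cass_pool = []
    for g in sim.genes:
        tx = g.transcripts[0]
        if len(tx.exons) >= 3:
            order = tx.exons if g.strand == "+" else tx.exons[::-1]
            for i in range(1, len(order) - 1):
                cass_pool.append((g, order, i))
    if n_cassette > len(cass_pool):
        raise ValueError("not enough internal exons for requested cassette events")
    pick = rng.choice(len(cass_pool), size=n_cassette, replace=False) if n_cassette else []
    for j, pi in enumerate(sorted(pick)):
        g, order, i = cass_pool[pi]
        c1, ex, c2 = order[i - 1], order[i], order[i + 1]
        psi = float(rng.uniform(*psi_range))
        delta = float(delta_choices[rng.integers(len(delta_choices))])
        delta = float(np.clip(psi + delta, 0, 100) - psi)
        eid = f"cass_{j + 1:04d}"
        tid = g.transcripts[0].transcript_id
        rows.append(
            dict(
                event_id=eid, gene_id=g.gene_id, event_type="cassette",
                chrom=g.chrom, strand=g.strand,
                c1_start=c1[0], c1_end=c1[1], ex_start=ex[0], ex_end=ex[1],
                c2_start=c2[0], c2_end=c2[1],
                up_intron_id=f"{tid}.i{i}", down_intron_id=f"{tid}.i{i + 1}",
            )
        )
        truths.append(TruthSpliceEffect(eid, "cassette", psi, delta))

    if ir_intron_ids is not None:
        chosen = list(ir_intron_ids)
        deltas = list(ir_deltas) if ir_deltas is not None else [0.0] * len(chosen)
    else:
        ids = sorted(introns_by_id)
        pick = rng.choice(len(ids), size=n_ir, replace=False) if n_ir else []
        chosen = [ids[i] for i in sorted(pick)]
        deltas = [float(delta_choices[rng.integers(len(delta_choices))]) for _ in chosen]
    for j, (iid, delta) in enumerate(zip(chosen, deltas)):
        iv = introns_by_id[iid]
        pir = float(rng.uniform(*pir_range))
        delta = float(np.clip(pir + delta, 0, 100) - pir)
        eid = f"ir_{j + 1:04d}"
        rows.append(
            dict(
                event_id=eid, gene_id=iv.gene_id, event_type="intron_retention",
                chrom=iv.chrom, strand=iv.strand,
                c1_start=-1, c1_end=-1, ex_start=iv.start, ex_end=iv.end,
                c2_start=-1, c2_end=-1, up_intron_id=iid, down_intron_id="",
            )
        )
        truths.append(TruthSpliceEffect(eid, "intron_retention", pir, delta, intron_id=iid))
    events = pd.DataFrame(rows)
    return events, truths


COUNT_COLS = ["inc_up", "inc_down", "exc", "e1i", "ie2", "e1e2"]


def simulate_splice_counts(
    truths: Sequence[TruthSpliceEffect],
    depth: int = 500,
    n_reps_per_condition: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample junction / boundary counts consistent with planted psi/pir.

    Cassette: inc_up, inc_down ~ Binomial(depth, psi/100) independently and
    exc ~ Binomial(depth, 1 - psi/100), so the psi estimator
    100*((inc_up+inc_down)/2) / ((inc_up+inc_down)/2 + exc) is consistent.
    Intron retention uses the same scheme with (e1i, ie2, e1e2) and pir.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for t in truths:
        for cond, level in (("control", t.psi_control), ("kd", t.psi_control + t.delta)):
            p = min(max(level / 100.0, 0.0), 1.0)
            for rep in range(1, n_reps_per_condition + 1):
                a = int(rng.binomial(depth, p))
                b = int(rng.binomial(depth, p))
                c = int(rng.binomial(depth, 1 - p))
                rec = dict(
                    event_id=t.event_id, event_type=t.event_type,
                    condition=cond, replicate=rep,
                    inc_up=0, inc_down=0, exc=0, e1i=0, ie2=0, e1e2=0,
                )
                if t.event_type == "intron_retention":
                    rec.update(e1i=a, ie2=b, e1e2=c)
                else:
                    rec.update(inc_up=a, inc_down=b, exc=c)
                rows.append(rec)
    return pd.DataFrame(rows)


def truth_effects_table(truths: Sequence[TruthSpliceEffect]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])


def simulate_gene_counts(
    sim: SimulatedGenome,
    n_samples: int = 6,
    seed: int = 0,
    mean_range: tuple[float, float] = (50.0, 2000.0),
    low_expr_frac: float = 0.0,
) -> pd.DataFrame:
    """Gene x sample RNA-seq count matrix (Poisson around lognormal means).

    A ``low_expr_frac`` fraction of genes gets a near-zero mean so the
    normalized-count expression filter has something to remove.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in sim.genes]
    lo, hi = np.log(mean_range[0]), np.log(mean_range[1])
    means = np.exp(rng.uniform(lo, hi, len(gene_ids)))
    n_low = int(round(low_expr_frac * len(gene_ids)))
    if n_low:
        low_idx = rng.choice(len(gene_ids), n_low, replace=False)
        means[low_idx] = 0.2
    size_factors = rng.uniform(0.7, 1.4, n_samples)
    mat = rng.poisson(np.outer(means, size_factors))
    cols = [f"s{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
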