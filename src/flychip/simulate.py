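"""Synthetic genomes, annotations and ChIP tag sets with planted truth.

The generator emulates the inputs of a whole-organism ChIP-seq study on a
compact genome: chromosomes carrying near-identical transposon-family copies
(which force genuinely multi-mapping 35-nt reads), protein-coding genes with
exon structure and expression levels, and mark-specific tag enrichment —
promoter-proximal footprints at configurable offsets, expression-scaled
gene-body signal, transposon-family affinities, and exon-side enrichment or
depletion at splice junctions. Every simulated read's true origin is recorded
so downstream recovery is testable without external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .models import GeneModel, Transcript, TransposonCopy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


class PlacementError(RuntimeError):
    """Raised when annotation features cannot be placed without overlap."""


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[np.clip(codes, 0, 3)].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# -------------------------------------------------------------- distributions


@dataclass(frozen=True)
class FragmentLengthDist:
    """Discrete probability mass over sheared-fragment lengths (bp)."""

    lengths: np.ndarray
    pmf: np.ndarray

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=int)
        pmf = np.asarray(self.pmf, dtype=float)
        if np.any(pmf < 0):
            raise ValueError("fragment-length masses must be non-negative")
        total = pmf.sum()
        if total <= 0:
            raise ValueError("fragment-length distribution has zero total mass")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "pmf", pmf / total)

    @classmethod
    def triangular(cls, low: int = 100, high: int = 500, mode: int = 200) -> "FragmentLengthDist":
        """Default fragment profile: triangular over the mono/di/poly-nucleosome
        size range seen on a shearing gel."""
        lengths = np.arange(low, high + 1)
        up = (lengths - low + 1.0) / (mode - low + 1.0)
        down = (high - lengths + 1.0) / (high - mode + 1.0)
        return cls(lengths, np.minimum(up, down))

    @classmethod
    def uniform(cls, low: int = 1, high: int = 500) -> "FragmentLengthDist":
        lengths = np.arange(low, high + 1)
        return cls(lengths, np.ones_like(lengths, dtype=float))

    @classmethod
    def constant(cls, length: int) -> "FragmentLengthDist":
        return cls(np.array([length]), np.array([1.0]))

    def survival(self, x: float) -> float:
        """P(fragment length > x)."""
        return float(self.pmf[self.lengths > x].sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.lengths, size=n, p=self.pmf)

    @property
    def min_length(self) -> int:
        return int(self.lengths[self.pmf > 0].min())


# --------------------------------------------------------------------- marks


@dataclass(frozen=True)
class JunctionSignal:
    """Additive enrichment (rate > 0) of read 5' ends near splice junctions,
    in transcription-direction offsets (negative = upstream of the junction)."""

    kind: str  # "exon_intron" | "intron_exon"
    offset: float = -90.0
    sigma: float = 10.0
    rate: float = 1.0
    slowing_only: bool = False


@dataclass(frozen=True)
class JunctionDepletion:
    """Multiplicative suppression of the local rate in a window around a
    junction (factor < 1 depletes)."""

    kind: str
    offset: float = -30.0
    halfwidth: float = 15.0
    factor: float = 0.1


@dataclass(frozen=True)
class MarkModel:
    """Planted tag-rate landscape of one chromatin mark.

    Rates are relative weights; the simulator normalizes them into an exact
    multinomial over the genome. A footprint offset f denotes read 5' ends
    concentrated in the 5-bp window [f, f+5) on the gene-oriented axis, so
    the sampled positions centre on f+2.
    """

    name: str
    background_rate: float = 1.0  # weight per bp, split across strands
    tss_offset: float = 0.0
    tss_sigma: float = 8.0
    tss_rate: float = 0.0  # weight per gene TSS
    tss_class_weights: Optional[Dict[str, float]] = None  # planted-class multipliers
    body_rate: float = 0.0  # weight per kb of gene body per expression unit
    body_class_weights: Optional[Dict[str, float]] = None
    family_affinity: Dict[str, float] = field(default_factory=dict)  # weight per kb of copy
    junction_signals: Tuple[JunctionSignal, ...] = ()
    junction_depletions: Tuple[JunctionDepletion, ...] = ()

    def __post_init__(self):
        rates = [self.background_rate, self.tss_rate, self.body_rate,
                 *self.family_affinity.values()] + [j.rate for j in self.junction_signals]
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be non-negative")
        if not (math.isfinite(self.tss_offset) and math.isfinite(self.tss_sigma)):
            raise ValueError("offsets must be finite")


def uniform_mark(name: str = "mock", background_rate: float = 1.0) -> MarkModel:
    return MarkModel(name=name, background_rate=background_rate)


def stalled_polii_mark(offset: float = 35.0, sigma: float = 8.0,
                       tss_rate: float = 30_000.0, body_rate: float = 800.0,
                       background: float = 1.0) -> MarkModel:
    """PolII model in which planted 'stalled' genes carry a strong promoter
    footprint and no body signal, 'elongating' genes a weaker footprint plus
    expression-scaled body signal, and 'none' genes only background.

    The default promoter footprint weight makes one stalled promoter capture
    on the order of a percent of the library on a megabase-scale world —
    i.e. a strong promoter-proximal peak well clear of the noise floor, as a
    real stalled promoter is.
    """
    return MarkModel(
        name="polII",
        background_rate=background,
        tss_offset=offset,
        tss_sigma=sigma,
        tss_rate=tss_rate,
        tss_class_weights={"stalled": 1.0, "elongating": 0.15, "none": 0.0},
        body_rate=body_rate,
        body_class_weights={"stalled": 0.0, "elongating": 1.0, "none": 0.0},
    )


def elongating_polii_mark(offset: float = 45.0, **kw) -> MarkModel:
    m = stalled_polii_mark(offset=offset, **kw)
    return replace(m, tss_class_weights={"stalled": 0.0, "elongating": 1.0, "none": 0.0})


# --------------------------------------------------------------------- world


@dataclass(frozen=True)
class WorldConfig:
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr2L": 1_000_000, "chr2R": 1_000_000})
    n_genes: int = 100
    gene_length: Tuple[int, int] = (2_000, 8_000)
    exons_per_gene: Tuple[int, int] = (1, 8)
    min_exon: int = 100
    min_intron: int = 80
    n_transposon_families: int = 3
    copies_per_family: int = 15
    consensus_length: Tuple[int, int] = (800, 1_500)
    family_identity: float = 0.95
    silent_fraction: float = 0.3
    stalled_fraction: float = 0.25  # of expressed genes
    expression_mu: float = 1.0  # lognormal parameters for expressed genes
    expression_sigma: float = 1.0
    slowing_fraction: float = 0.15  # of expressed multi-exon genes
    extra_variant_prob: float = 0.3
    feature_gap: int = 500
    max_place_tries: int = 200

    def __post_init__(self):
        if self.n_genes < 0 or self.n_transposon_families < 0 or self.copies_per_family < 0:
            raise ValueError("config counts must be non-negative")
        if any(l < 10_000 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 10 kb")


@dataclass
class SyntheticWorld:
    """A generated genome, annotation, expression table and planted truth."""

    chromosomes: Dict[str, str]
    genes: List[GeneModel]
    transposon_copies: List[TransposonCopy]
    expression: Dict[str, float]
    truth: pd.DataFrame  # index gene_id; columns class, expression, slowing
    config: WorldConfig
    seed: int
    _codes: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def layout(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            self._codes[chrom] = encode(self.chromosomes[chrom])
        return self._codes[chrom]

    def genes_by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    # -- exports -------------------------------------------------------------
    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_fasta(self.chromosomes, out / "genome.fa")
        fio.write_gff3(self.genes, out / "genes.gff3")
        fio.write_bed6(self.transposon_copies, out / "transposons.bed")
        pd.Series(self.expression, name="expression").rename_axis("gene_id").to_csv(
            out / "expression.tsv", sep="\t")
        self.truth.to_csv(out / "truth.tsv", sep="\t")


def _place_interval(rng, length: int, chrom_lengths: Dict[str, int],
                    occupied: Dict[str, List[Tuple[int, int]]], gap: int,
                    max_tries: int) -> Tuple[str, int]:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        limit = chrom_lengths[chrom] - length - gap
        if limit <= gap:
            continue
        start = int(rng.integers(gap, limit))
        if all(start + length + gap <= s or start >= e + gap for s, e in occupied[chrom]):
            occupied[chrom].append((start, start + length))
            return chrom, start
    raise PlacementError("could not place feature without overlap; reduce feature "
                         "counts or lengths, or enlarge the genome")


def _make_transcript(rng, gene_id: str, tx_id: str, start: int, length: int,
                     n_exons: int, cfg: WorldConfig) -> Transcript:
    end = start + length
    if n_exons == 1:
        exons = ((start, end),)
    else:
        # split the span into alternating exon/intron blocks of random size
        n_blocks = 2 * n_exons - 1
        mins = np.array([cfg.min_exon if i % 2 == 0 else cfg.min_intron
                         for i in range(n_blocks)])
        spare = length - mins.sum()
        if spare < 0:
            n_exons = max(1, (length + cfg.min_intron) // (cfg.min_exon + cfg.min_intron))
            return _make_transcript(rng, gene_id, tx_id, start, length, n_exons, cfg)
        extra = rng.multinomial(spare, np.full(n_blocks, 1.0 / n_blocks))
        sizes = mins + extra
        bounds = start + np.concatenate([[0], np.cumsum(sizes)])
        exons = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_blocks, 2))
    cds = (exons[0][0] + (exons[0][1] - exons[0][0]) // 2,
           exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2)
    return Transcript(tx_id, start, end, exons, cds)


def build_world(config: WorldConfig = WorldConfig(), seed: int = 0) -> SyntheticWorld:
    """Generate a deterministic synthetic world with planted truth."""
    rng = np.random.default_rng(seed)
    chrom_codes = {c: rng.integers(0, 4, size=l, dtype=np.uint8)
                   for c, l in config.chrom_lengths.items()}
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.chrom_lengths}

    # transposon families: mutate a consensus at rate (1 - identity)
    copies: List[TransposonCopy] = []
    for f in range(config.n_transposon_families):
        fam = f"TE{f + 1}"
        clen = int(rng.integers(*config.consensus_length))
        consensus = rng.integers(0, 4, size=clen, dtype=np.uint8)
        for c in range(config.copies_per_family):
            chrom, start = _place_interval(rng, clen, config.chrom_lengths, occupied,
                                           config.feature_gap, config.max_place_tries)
            seq = consensus.copy()
            sub_rate = 1.0 - config.family_identity
            if sub_rate > 0:
                mut = rng.random(clen) < sub_rate
                seq[mut] = (seq[mut] + rng.integers(1, 4, size=mut.sum())) % 4
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seq if strand == "+" else (3 - seq)[::-1]
            chrom_codes[chrom][start:start + clen] = placed
            copies.append(TransposonCopy(fam, chrom, start, start + clen, strand,
                                         config.family_identity))

    # genes
    genes: List[GeneModel] = []
    for i in range(config.n_genes):
        gid = f"gene{i + 1:04d}"
        length = int(rng.integers(*config.gene_length))
        chrom, start = _place_interval(rng, length, config.chrom_lengths, occupied,
                                       config.feature_gap, config.max_place_tries)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        primary = _make_transcript(rng, gid, f"{gid}.t1", start, length, n_exons, cfg=config)
        transcripts = [primary]
        if len(primary.exons) >= 3 and rng.random() < config.extra_variant_prob:
            # splice variant skipping one internal exon
            skip = int(rng.integers(1, len(primary.exons) - 1))
            exons = tuple(e for j, e in enumerate(primary.exons) if j != skip)
            transcripts.append(Transcript(f"{gid}.t2", primary.start, primary.end,
                                          exons, primary.cds))
        genes.append(GeneModel(gid, chrom, strand, tuple(transcripts)))

    # expression and planted classes
    gene_ids = [g.gene_id for g in genes]
    silent = rng.random(len(genes)) < config.silent_fraction
    expr = np.where(silent, 0.0,
                    rng.lognormal(config.expression_mu, config.expression_sigma, len(genes)))
    klass = np.where(silent, "none",
                     np.where(rng.random(len(genes)) < config.stalled_fraction,
                              "stalled", "elongating"))
    multi_exon = np.array([max(len(t.exons) for t in g.transcripts) >= 2 for g in genes])
    slowing = (~silent) & multi_exon & (rng.random(len(genes)) < config.slowing_fraction)
    truth = pd.DataFrame({"class": klass, "expression": expr, "slowing": slowing},
                         index=pd.Index(gene_ids, name="gene_id"))

    chromosomes = {c: decode(codes) for c, codes in chrom_codes.items()}
    return SyntheticWorld(chromosomes, genes, copies, dict(zip(gene_ids, expr)),
                          truth, config, seed, _codes=chrom_codes)


# --------------------------------------------------------------- tag sampling


@dataclass
class SimulatedTags:
    """A simulated read set plus its true-origin table."""

    mark: str
    reads: List[Tuple[str, str]]  # (read_id, sequence)
    origins: pd.DataFrame  # read_id, chrom, pos (5'), strand, frag_len

    @property
    def n_tags(self) -> int:
        return len(self.reads)

    def to_fastq(self, path) -> None:
        fio.write_fastq(self.reads, path)


def _junction_anchors_for_gene(gene: GeneModel, kind: str) -> List[int]:
    """Transcription-direction junction anchors: the genomic position of the
    first base downstream of the junction boundary (offset 0)."""
    anchors = []
    t = gene.transcripts[0]
    exons = t.exons
    if len(exons) < 2:
        return anchors
    if kind == "exon_intron":
        if gene.strand == "+":
            anchors = [e for (_, e) in exons[:-1]]
        else:
            anchors = [s - 1 for (s, _) in exons[1:]]
    elif kind == "intron_exon":
        if gene.strand == "+":
            anchors = [s for (s, _) in exons[1:]]
        else:
            anchors = [e - 1 for (_, e) in exons[:-1]]
    else:
        raise ValueError(f"unknown junction kind {kind!r}")
    return anchors


def junction_anchor_table(genes: Sequence[GeneModel], kind: str,
                          min_tss_distance: int = 0) -> pd.DataFrame:
    """All internal junction anchors of the given kind, one row per junction
    (gene_id, chrom, pos, strand). Junctions closer than ``min_tss_distance``
    to the gene's TSS are excluded."""
    rows = []
    for g in genes:
        tss = g.tss
        for pos in _junction_anchors_for_gene(g, kind):
            if abs(pos - tss) < min_tss_distance:
                continue
            rows.append((g.gene_id, g.chrom, pos, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])


def _gauss_add(arr: np.ndarray, center: float, sigma: float, weight: float) -> None:
    lo = max(0, int(center - 4 * sigma))
    hi = min(len(arr), int(center + 4 * sigma) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    w = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    s = w.sum()
    if s > 0:
        arr[lo:hi] += weight * w / s


def _rate_landscape(world: SyntheticWorld, model: MarkModel) -> Dict[str, np.ndarray]:
    """Per-chromosome planted rate of read 5' starts (strands share each
    component equally; returned per chromosome, per-strand split applied at
    sampling time)."""
    rates = {c: np.full(l, float(model.background_rate), dtype=np.float64)
             for c, l in world.layout.items()}

    for g in world.genes:
        cls = world.truth.loc[g.gene_id, "class"]
        arr = rates[g.chrom]
        d = g.direction
        if model.tss_rate > 0:
            mult = 1.0 if model.tss_class_weights is None else \
                model.tss_class_weights.get(cls, 1.0)
            if mult > 0:
                for tss in g.tss_positions():
                    center = tss + d * (model.tss_offset + 2.0)
                    _gauss_add(arr, center, model.tss_sigma, model.tss_rate * mult)
        if model.body_rate > 0:
            mult = 1.0 if model.body_class_weights is None else \
                model.body_class_weights.get(cls, 1.0)
            expr = world.expression[g.gene_id]
            if mult > 0 and expr > 0:
                t = g.transcripts[0]
                weight = model.body_rate * mult * expr * (t.end - t.start) / 1000.0
                arr[t.start:t.end] += weight / (t.end - t.start)
        for js in model.junction_signals:
            if js.slowing_only and not world.truth.loc[g.gene_id, "slowing"]:
                continue
            if world.expression[g.gene_id] <= 0:
                continue
            for j in _junction_anchors_for_gene(g, js.kind):
                center = j + d * (js.offset + 2.0)
                _gauss_add(arr, center, js.sigma, js.rate)

    for c in world.transposon_copies:
        aff = model.family_affinity.get(c.family, 0.0)
        if aff > 0:
            weight = aff * c.length / 1000.0
            rates[c.chrom][c.start:c.end] += weight / c.length

    # multiplicative depletions applied last
    for g in world.genes:
        if world.expression[g.gene_id] <= 0:
            continue
        d = g.direction
        for jd in model.junction_depletions:
            for j in _junction_anchors_for_gene(g, jd.kind):
                center = j + d * (jd.offset + 2.0)
                lo = max(0, int(center - jd.halfwidth))
                hi = min(world.layout[g.chrom], int(center + jd.halfwidth) + 1)
                if hi > lo:
                    rates[g.chrom][lo:hi] *= jd.factor
    return rates


def _extract_reads(world: SyntheticWorld, chrom: str, pos: np.ndarray,
                   strand_plus: np.ndarray, read_len: int) -> np.ndarray:
    codes = world.codes(chrom)
    out = np.empty((len(pos), read_len), dtype=np.uint8)
    offs = np.arange(read_len)
    plus = strand_plus
    if plus.any():
        idx = pos[plus, None] + offs[None, :]
        out[plus] = codes[idx]
    minus = ~plus
    if minus.any():
        idx = pos[minus, None] - offs[None, :]
        out[minus] = 3 - codes[idx]
    return out


def _sample_positions(rng: np.random.Generator, rate: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    lo = rate.min()
    if lo == rate.max():  # uniform fast path
        return rng.integers(0, len(rate), size=n)
    return rng.choice(len(rate), size=n, p=rate / rate.sum())


def _sample_tags(world: SyntheticWorld, rates: Dict[str, np.ndarray], n_tags: int,
                 frag: FragmentLengthDist, read_len: int, error_rate: float,
                 seed: int, mark: str, emit_reads: bool = True) -> SimulatedTags:
    if sum(world.layout.values()) == 0:
        raise ValueError("zero-length genome")
    if read_len > frag.min_length:
        raise ValueError("read length exceeds the minimum supported fragment length")
    rng = np.random.default_rng(seed)
    chroms = list(rates)
    if n_tags == 0:
        empty = pd.DataFrame(columns=["read_id", "chrom", "pos", "strand", "frag_len"])
        return SimulatedTags(mark, [], empty)

    # exact multinomial over (chromosome, strand); rates split equally by strand
    totals = np.array([rates[c].sum() for c in chroms], dtype=float)
    if totals.sum() <= 0:
        raise ValueError("planted rate landscape is identically zero")
    weights = np.repeat(totals / 2.0, 2)
    counts = rng.multinomial(n_tags, weights / weights.sum())

    recs_chrom, recs_pos, recs_strand = [], [], []
    for i, c in enumerate(chroms):
        L = world.layout[c]
        for s_i, strand in enumerate("+-"):
            need = counts[2 * i + s_i]
            got: List[np.ndarray] = []
            n_have = 0
            while n_have < need:
                draw = _sample_positions(rng, rates[c], need - n_have)
                # discard reads running off the chromosome end and resample
                ok = draw + read_len <= L if strand == "+" else draw >= read_len - 1
                draw = draw[ok]
                got.append(draw)
                n_have += len(draw)
            pos = np.concatenate(got) if got else np.empty(0, dtype=int)
            recs_chrom.extend([c] * need)
            recs_pos.append(pos)
            recs_strand.extend([strand] * need)

    pos_all = np.concatenate(recs_pos).astype(int)
    chrom_all = np.array(recs_chrom)
    strand_all = np.array(recs_strand)
    order = rng.permutation(len(pos_all))
    pos_all, chrom_all, strand_all = pos_all[order], chrom_all[order], strand_all[order]
    frag_len = frag.sample(rng, len(pos_all))

    read_ids = [f"{mark}_{seed}_{i:07d}" for i in range(len(pos_all))]
    if emit_reads:
        seqs = np.empty((len(pos_all), read_len), dtype=np.uint8)
        for c in chroms:
            m = chrom_all == c
            if m.any():
                seqs[m] = _extract_reads(world, c, pos_all[m], strand_all[m] == "+", read_len)
        if error_rate > 0:
            err = rng.random(seqs.shape) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            seqs[err] = (seqs[err] + shift) % 4
        reads = [(rid, decode(row)) for rid, row in zip(read_ids, seqs)]
    else:
        reads = []
    origins = pd.DataFrame({"read_id": read_ids, "chrom": chrom_all,
                            "pos": pos_all, "strand": strand_all, "frag_len": frag_len})
    return SimulatedTags(mark, reads, origins)


def simulate_mark_tags(world: SyntheticWorld, model: MarkModel, n_tags: int,
                       frag: Optional[FragmentLengthDist] = None, read_len: int = 35,
                       error_rate: float = 0.0, seed: int = 0,
                       emit_reads: bool = True) -> SimulatedTags:
    """Draw ``n_tags`` reads (first ``read_len`` bases from the 5' end of each
    sampled fragment) from the mark's planted rate landscape. With
    ``emit_reads=False`` only the true-origin table is materialized (faster
    when the reads themselves are not needed)."""
    if n_tags < 0:
        raise ValueError("n_tags must be >= 0")
    frag = frag or FragmentLengthDist.triangular()
    rates = _rate_landscape(world, model)
    return _sample_tags(world, rates, n_tags, frag, read_len, error_rate, seed,
                        model.name, emit_reads)


def simulate_control_tags(world: SyntheticWorld, n_tags: int,
                          frag: Optional[FragmentLengthDist] = None, seed: int = 0,
                          read_len: int = 35, error_rate: float = 0.0,
                          bias: Optional[Dict[str, np.ndarray]] = None,
                          emit_reads: bool = True) -> SimulatedTags:
    """Mock-ChIP control: uniform genome-wide fragment starts, optionally
    modulated by a smooth per-bp accessibility bias."""
    frag = frag or FragmentLengthDist.triangular()
    if bias is None:
        rates = {c: np.ones(l, dtype=np.float64) for c, l in world.layout.items()}
    else:
        rates = {c: np.asarray(bias[c], dtype=np.float64) for c in world.layout}
    return _sample_tags(world, rates, n_tags, frag, read_len, error_rate, seed,
                        "mock", emit_reads)
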