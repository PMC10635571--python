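"""Seeded synthetic transcriptome and alignment-record generator.

The simulator emulates the statistical structure of a protein-mediated
proximity-ligation chimeric-read library *at alignment level*: it emits SAM
records directly (no sequences, no aligner), because the analysis pipeline
starts downstream of read mapping.  It plants

* intramolecular duplexes (two arms within one gene, supported by several
  chimeras with jittered, hence distinct, termini),
* intermolecular gene pairs enriched over a random-ligation background,
* a degree-preserving random-ligation background (arm endpoints drawn per
  gene proportionally to expression),
* splice-junction gapped reads (decoys that must be discarded),
* exact-coordinate PCR duplicates and low-MAPQ decoys,

and records every emitted read's generating mechanism in a ground-truth
table so that downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .annotation import GenomeAnnotation, GeneRecord, TranscriptRecord

__all__ = [
    "SimConfig",
    "SimConfigError",
    "PlantedDuplex",
    "PlantedTransPair",
    "SimAlignment",
    "simulate_annotation",
    "plant_duplexes",
    "simulate_reads",
    "expression_weights",
    "write_sam",
    "write_truth",
    "read_truth",
]

# Mechanism labels used in the truth table.
MECH_NONCHIMERIC = "nonchimeric"
MECH_SPLICE_GAP = "splice_gap"
MECH_PLANTED_DUPLEX = "planted_duplex"
MECH_BACKGROUND_INTRA = "background_intra"
MECH_PLANTED_TRANS = "planted_trans"
MECH_BACKGROUND_TRANS = "background_trans"
MECH_DUPLICATE = "duplicate"
MECH_LOW_MAPQ = "low_mapq_decoy"

CHIMERA_MECHANISMS = frozenset(
    {MECH_PLANTED_DUPLEX, MECH_BACKGROUND_INTRA, MECH_PLANTED_TRANS, MECH_BACKGROUND_TRANS}
)


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedDuplex:
    gene_id: str
    arm_a: Tuple[int, int]
    arm_b: Tuple[int, int]
    n_support: int


@dataclass(frozen=True)
class PlantedTransPair:
    gene_a: str
    gene_b: str
    enrichment_factor: float


@dataclass
class SimConfig:
    """Simulation parameters; every run is fully determined by ``seed``.

    ``n_chimeric_reads`` is the number of *background* (random-ligation)
    chimeras; if None it is derived from ``background_ligation_rate`` so that
    background chimeras make up that fraction of all emitted chimeras.
    """

    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {
            "mRNA": 40,
            "lncRNA": 12,
            "snRNA": 4,
            "snoRNA": 4,
            "pseudogene": 2,
            "other": 2,
        }
    )
    exon_length_range: Tuple[int, int] = (120, 400)
    intron_length_range: Tuple[int, int] = (100, 400)
    n_exons_range: Tuple[int, int] = (2, 5)
    intergene_gap_range: Tuple[int, int] = (200, 800)
    expression_lognorm: Tuple[float, float] = (0.0, 1.0)  # (mu, sigma) of ln weight
    planted_duplexes: Optional[Sequence[PlantedDuplex]] = None
    planted_trans_pairs: Optional[Sequence[PlantedTransPair]] = None
    background_ligation_rate: float = 0.05
    background_trans_fraction: float = 0.5
    n_nonchimeric_reads: int = 5000
    n_chimeric_reads: Optional[int] = None
    n_splice_gapped_reads: int = 500
    duplicate_rate: float = 0.1
    low_mapq_rate: float = 0.05
    arm_length_range: Tuple[int, int] = (18, 40)
    read_length_range: Tuple[int, int] = (30, 60)
    gap_encoded_fraction: float = 0.5  # intra chimeras emitted as one gapped line
    contig: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        for name in ("background_ligation_rate", "background_trans_fraction",
                     "duplicate_rate", "low_mapq_rate", "gap_encoded_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        if self.arm_length_range[0] < 15:
            raise SimConfigError("minimum arm length is 15 bp")
        for name in ("exon_length_range", "intron_length_range", "n_exons_range",
                     "arm_length_range", "read_length_range", "intergene_gap_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise SimConfigError(f"{name} must satisfy 0 < lo <= hi")
        if self.n_exons_range[0] < 2:
            raise SimConfigError("every gene must have a multi-exon transcript")
        for k in self.n_genes:
            if self.n_genes[k] < 0:
                raise SimConfigError("gene counts must be non-negative")


@dataclass(frozen=True)
class SimAlignment:
    """One SAM alignment line; a chimeric read spans two of these."""

    read_id: str
    contig: str
    strand: str
    blocks: Tuple[Tuple[int, int], ...]  # matched blocks; gaps between are N
    mapq: int = 60
    supplementary: bool = False
    paired: bool = False
    mate_index: int = 0  # 0 = read1/unpaired, 1 = read2

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def _rng_streams(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# -- annotation ----------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Lay non-overlapping multi-exon genes of the configured classes on one contig."""
    cfg.validate()
    rng = _rng_streams(cfg.seed, 4)[0]
    classes: List[str] = []
    for cls, n in sorted(cfg.n_genes.items()):
        classes.extend([cls] * n)
    rng.shuffle(classes)

    genes: List[GeneRecord] = []
    transcripts: List[TranscriptRecord] = []
    cursor = 1000
    for i, cls in enumerate(classes):
        gene_id = f"G{i:04d}_{cls}"
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for j in range(n_exons):
            elen = int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if j < n_exons - 1:
                pos += int(
                    rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)
                )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig=cfg.contig,
                start=exons[0][0],
                end=exons[-1][1],
                strand=strand,
                biotype_class=cls,
                biotype={"mRNA": "protein_coding", "pseudogene": "processed_pseudogene"}.get(cls, cls),
            )
        )
        transcripts.append(
            TranscriptRecord(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                contig=cfg.contig,
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursor = exons[-1][1] + int(
            rng.integers(cfg.intergene_gap_range[0], cfg.intergene_gap_range[1] + 1)
        )
    contig_len = cursor + 1000
    return GenomeAnnotation(genes, transcripts, [(cfg.contig, contig_len)])


def expression_weights(cfg: SimConfig, ann: GenomeAnnotation) -> Dict[str, float]:
    """Per-gene expression weights (log-normal, seeded); the sampling
    probabilities behind every expression-weighted draw in simulate_reads."""
    rng = _rng_streams(cfg.seed, 4)[1]
    mu, sigma = cfg.expression_lognorm
    return {
        g.gene_id: float(w)
        for g, w in zip(ann.genes, rng.lognormal(mu, sigma, size=len(ann.genes)))
    }


ARM_MARGIN = 8  # bp kept clear of exon boundaries so jittered arms stay exonic


def plant_duplexes(
    ann: GenomeAnnotation,
    n_duplexes: int,
    n_support: int,
    rng: np.random.Generator,
    arm_length: int = 25,
) -> List[PlantedDuplex]:
    """Choose duplexes to plant: both arms inside (distinct) exons of one gene.

    Arms keep an ARM_MARGIN from exon boundaries so that +/-5 bp terminus
    jitter can never make a gap-encoded chimera's gap coincide with an
    annotated intron.
    """
    need = arm_length + 2 * ARM_MARGIN
    candidates = []
    for t in ann.transcripts:
        wide = [e for e in t.exons if e[1] - e[0] >= need]
        if len(wide) >= 2:
            candidates.append((t, wide))
    if not candidates:
        raise SimConfigError("no transcript has two exons wide enough to plant duplexes")
    out: List[PlantedDuplex] = []
    for _ in range(n_duplexes):
        t, wide = candidates[int(rng.integers(len(candidates)))]
        i, j = sorted(rng.choice(len(wide), size=2, replace=False))
        arms = []
        for e in (wide[i], wide[j]):
            lo = e[0] + ARM_MARGIN
            hi = e[1] - ARM_MARGIN - arm_length
            s = int(rng.integers(lo, hi + 1))
            arms.append((s, s + arm_length))
        out.append(PlantedDuplex(t.gene_id, arms[0], arms[1], n_support))
    return out


# -- reads ---------------------------------------------------------------

class _Emitter:
    def __init__(self):
        self.records: List[SimAlignment] = []
        self.truth_rows: List[Tuple[str, str, str]] = []
        self._i = 0

    def next_id(self) -> str:
        self._i += 1
        return f"r{self._i:07d}"

    def emit(self, mechanism: str, key: str, alignments: List[SimAlignment]) -> str:
        self.records.extend(alignments)
        self.truth_rows.append((alignments[0].read_id, mechanism, key))
        return alignments[0].read_id


def _sample_exonic_interval(
    rng: np.random.Generator, t: TranscriptRecord, length: int
) -> Optional[Tuple[int, int]]:
    exons = [e for e in t.exons if e[1] - e[0] >= length]
    if not exons:
        return None
    lens = np.array([e[1] - e[0] for e in exons], dtype=float)
    e = exons[int(rng.choice(len(exons), p=lens / lens.sum()))]
    s = int(rng.integers(e[0], e[1] - length + 1))
    return (s, s + length)


def _pick_gene(rng, gene_ids, probs) -> str:
    return gene_ids[int(rng.choice(len(gene_ids), p=probs))]


def _intra_chimera_alignments(
    em: _Emitter,
    rng: np.random.Generator,
    contig: str,
    strand: str,
    arm_a: Tuple[int, int],
    arm_b: Tuple[int, int],
    gap_encoded: bool,
) -> List[SimAlignment]:
    rid = em.next_id()
    if gap_encoded and arm_b[0] - arm_a[1] >= 1:
        return [SimAlignment(rid, contig, strand, (arm_a, arm_b))]
    return [
        SimAlignment(rid, contig, strand, (arm_a,)),
        SimAlignment(rid, contig, strand, (arm_b,), supplementary=True),
    ]


def simulate_reads(
    cfg: SimConfig, ann: GenomeAnnotation
) -> Tuple[List[SimAlignment], pd.DataFrame]:
    """Emit alignment records plus the ground-truth mechanism table.

    Returns records (SimAlignment stream, one or two per read) and a
    DataFrame with columns read_id / mechanism / key.
    """
    cfg.validate()
    rng = _rng_streams(cfg.seed, 4)[2]
    weights = expression_weights(cfg, ann)
    gene_ids = sorted(weights)
    w = np.array([weights[g] for g in gene_ids])
    probs = w / w.sum()
    tx_by_gene = {t.gene_id: t for t in ann.transcripts}
    em = _Emitter()

    planted_duplexes = list(cfg.planted_duplexes or [])
    planted_pairs = list(cfg.planted_trans_pairs or [])
    for pd_ in planted_duplexes:
        if not ann.has_gene(pd_.gene_id):
            raise SimConfigError(f"planted duplex in unknown gene {pd_.gene_id}")
        if pd_.arm_a[1] > pd_.arm_b[0] and pd_.arm_b[1] > pd_.arm_a[0]:
            raise SimConfigError(f"planted duplex arms overlap in {pd_.gene_id}")
        g = ann.gene(pd_.gene_id)
        for arm in (pd_.arm_a, pd_.arm_b):
            if arm[0] < g.start or arm[1] > g.end:
                raise SimConfigError(f"planted arm outside gene {pd_.gene_id}")

    # -- non-chimeric exonic reads
    for _ in range(cfg.n_nonchimeric_reads):
        gid = _pick_gene(rng, gene_ids, probs)
        t = tx_by_gene[gid]
        length = int(rng.integers(cfg.read_length_range[0], cfg.read_length_range[1] + 1))
        iv = _sample_exonic_interval(rng, t, length)
        if iv is None:
            continue
        rid = em.next_id()
        em.emit(MECH_NONCHIMERIC, gid, [SimAlignment(rid, t.contig, t.strand, (iv,))])

    # -- splice-junction gapped reads (decoys)
    spliceable = [t for t in ann.transcripts if t.introns]
    for _ in range(cfg.n_splice_gapped_reads):
        t = spliceable[int(rng.integers(len(spliceable)))]
        introns = t.introns
        k = int(rng.integers(len(introns)))
        donor, acceptor = introns[k]
        left_exon = next(e for e in t.exons if e[1] == donor)
        right_exon = next(e for e in t.exons if e[0] == acceptor)
        llen = min(int(rng.integers(*cfg.arm_length_range)), left_exon[1] - left_exon[0])
        rlen = min(int(rng.integers(*cfg.arm_length_range)), right_exon[1] - right_exon[0])
        blocks = ((donor - llen, donor), (acceptor, acceptor + rlen))
        rid = em.next_id()
        em.emit(MECH_SPLICE_GAP, t.gene_id, [SimAlignment(rid, t.contig, t.strand, blocks)])

    # -- planted intramolecular duplexes, jittered distinct termini
    n_planted_chimeras = 0
    for d_idx, d in enumerate(planted_duplexes):
        g = ann.gene(d.gene_id)
        seen = set()
        for _ in range(d.n_support):
            for _attempt in range(200):
                jit = rng.integers(-5, 6, size=4)
                arm_a = (d.arm_a[0] + int(jit[0]), d.arm_a[1] + int(jit[1]))
                arm_b = (d.arm_b[0] + int(jit[2]), d.arm_b[1] + int(jit[3]))
                key = (arm_a, arm_b)
                if key not in seen and arm_a[1] < arm_b[0]:
                    seen.add(key)
                    break
            alns = _intra_chimera_alignments(
                em, rng, g.contig, g.strand, arm_a, arm_b,
                gap_encoded=rng.random() < cfg.gap_encoded_fraction,
            )
            em.emit(MECH_PLANTED_DUPLEX, f"{d.gene_id}:{d_idx}", alns)
            n_planted_chimeras += 1

    # -- planted trans pairs: contacts beyond random-ligation expectation
    n_background = cfg.n_chimeric_reads
    if n_background is None:
        rate = cfg.background_ligation_rate
        n_planted_total = n_planted_chimeras  # trans extras added below scale with this
        n_background = int(round(rate / (1.0 - rate) * max(n_planted_total, 1))) if rate > 0 else 0
    n_bg_trans = int(round(n_background * cfg.background_trans_fraction))
    n_bg_intra = n_background - n_bg_trans

    idx = {g: i for i, g in enumerate(gene_ids)}
    for p_idx, pair in enumerate(planted_pairs):
        for gid in (pair.gene_a, pair.gene_b):
            if not ann.has_gene(gid):
                raise SimConfigError(f"planted trans pair references unknown gene {gid}")
        pa, pb = probs[idx[pair.gene_a]], probs[idx[pair.gene_b]]
        expected_bg = n_bg_trans * 2.0 * pa * pb
        n_extra = int(round(max(pair.enrichment_factor - 1.0, 0.0) * expected_bg))
        for _ in range(n_extra):
            alns = _trans_chimera(em, rng, cfg, ann, tx_by_gene, pair.gene_a, pair.gene_b)
            if alns:
                key = "|".join(sorted((pair.gene_a, pair.gene_b)))
                em.emit(MECH_PLANTED_TRANS, key, alns)

    # -- background intra chimeras
    emitted = 0
    while emitted < n_bg_intra:
        gid = _pick_gene(rng, gene_ids, probs)
        t = tx_by_gene[gid]
        la = int(rng.integers(*cfg.arm_length_range))
        lb = int(rng.integers(*cfg.arm_length_range))
        a = _sample_exonic_interval(rng, t, la)
        b = _sample_exonic_interval(rng, t, lb)
        if a is None or b is None:
            continue
        a, b = sorted((a, b))
        if a[1] >= b[0]:  # overlapping or abutting arms: redraw
            continue
        # gap-encoding must not fake a splice junction
        gap_ok = (a[1], b[0]) not in set(t.introns)
        alns = _intra_chimera_alignments(
            em, rng, t.contig, t.strand, a, b,
            gap_encoded=gap_ok and rng.random() < cfg.gap_encoded_fraction,
        )
        em.emit(MECH_BACKGROUND_INTRA, gid, alns)
        emitted += 1

    # -- background trans chimeras (degree-preserving: both arms ~ expression)
    emitted = 0
    while emitted < n_bg_trans:
        ga = _pick_gene(rng, gene_ids, probs)
        gb = _pick_gene(rng, gene_ids, probs)
        if ga == gb:
            continue
        alns = _trans_chimera(em, rng, cfg, ann, tx_by_gene, ga, gb)
        if alns is None:
            continue
        em.emit(MECH_BACKGROUND_TRANS, "|".join(sorted((ga, gb))), alns)
        emitted += 1

    # -- low-MAPQ decoys (filtered by the MAPQ<30 rule downstream)
    n_base = len(em.truth_rows)
    n_decoys = int(round(cfg.low_mapq_rate * n_base))
    for k in range(n_decoys):
        if k % 2 == 0:
            gid = _pick_gene(rng, gene_ids, probs)
            t = tx_by_gene[gid]
            iv = _sample_exonic_interval(rng, t, cfg.read_length_range[0])
            if iv is None:
                continue
            rid = em.next_id()
            em.emit(MECH_LOW_MAPQ, gid,
                    [SimAlignment(rid, t.contig, t.strand, (iv,), mapq=10)])
        else:
            ga = _pick_gene(rng, gene_ids, probs)
            gb = _pick_gene(rng, gene_ids, probs)
            if ga == gb:
                continue
            alns = _trans_chimera(em, rng, cfg, ann, tx_by_gene, ga, gb)
            if alns is None:
                continue
            alns = [replace(a, mapq=10) for a in alns]
            em.emit(MECH_LOW_MAPQ, "|".join(sorted((ga, gb))), alns)

    # -- exact-coordinate PCR duplicates
    by_read: Dict[str, List[SimAlignment]] = {}
    for a in em.records:
        by_read.setdefault(a.read_id, []).append(a)
    base_rows = list(em.truth_rows)
    for read_id, _mech, _key in base_rows:
        if rng.random() < cfg.duplicate_rate:
            rid = em.next_id()
            copies = [replace(a, read_id=rid) for a in by_read[read_id]]
            em.emit(MECH_DUPLICATE, read_id, copies)

    truth = pd.DataFrame(em.truth_rows, columns=["read_id", "mechanism", "key"])
    return em.records, truth


def _trans_chimera(em, rng, cfg, ann, tx_by_gene, gene_a, gene_b):
    la = int(rng.integers(*cfg.arm_length_range))
    lb = int(rng.integers(*cfg.arm_length_range))
    ta, tb = tx_by_gene[gene_a], tx_by_gene[gene_b]
    a = _sample_exonic_interval(rng, ta, la)
    b = _sample_exonic_interval(rng, tb, lb)
    if a is None or b is None:
        return None
    rid = em.next_id()
    return [
        SimAlignment(rid, ta.contig, ta.strand, (a,)),
        SimAlignment(rid, tb.contig, tb.strand, (b,), supplementary=True),
    ]


# -- SAM / truth I/O -----------------------------------------------------

def _cigar(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ops: List[Tuple[int, int]] = []
    prev_end = None
    for (s, e) in blocks:
        if prev_end is not None:
            ops.append((3, s - prev_end))  # N
        ops.append((0, e - s))  # M
        prev_end = e
    return ops


def write_sam(records: Sequence[SimAlignment], ann: GenomeAnnotation, path: str) -> None:
    """Write records as a valid SAM with @SQ header lines.

    Chimeric reads appear as two lines sharing a QNAME, the 3' segment
    flagged supplementary, with reciprocal SA tags.
    """
    names = [c for c, _ in ann.contigs]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in ann.contigs],
        }
    )
    by_read: Dict[str, List[SimAlignment]] = {}
    order: List[str] = []
    for a in records:
        if a.end > dict(ann.contigs)[a.contig]:
            raise SimConfigError(f"alignment beyond contig end: {a}")
        if a.read_id not in by_read:
            order.append(a.read_id)
        by_read.setdefault(a.read_id, []).append(a)

    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rid in order:
            group = by_read[rid]
            for a in group:
                seg = pysam.AlignedSegment(header)
                seg.query_name = a.read_id
                seg.reference_id = names.index(a.contig)
                seg.reference_start = a.start
                seg.mapping_quality = a.mapq
                seg.cigartuples = _cigar(a.blocks)
                flag = 0
                if a.strand == "-":
                    flag |= 16
                if a.supplementary:
                    flag |= 2048
                if a.paired:
                    flag |= 1 | (64 if a.mate_index == 0 else 128)
                seg.flag = flag
                seg.query_sequence = None
                if len(group) == 2:
                    other = group[0] if a is group[1] else group[1]
                    cig = "".join(
                        f"{n}{'MN'[op == 3]}" for op, n in _cigar(other.blocks)
                    )
                    seg.set_tag(
                        "SA",
                        f"{other.contig},{other.start + 1},{other.strand},{cig},{other.mapq},0;",
                    )
                out.write(seg)


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
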