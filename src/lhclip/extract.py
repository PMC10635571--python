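"""Chimeric-read extraction from alignment records.

The chimeric-read set is assembled from two sources: chimerically mapped
reads (two alignment segments sharing a read id, one supplementary) and
gapped reads whose N-gap is *not* an annotated intron.  Records with
mapping quality below 30 or flagged secondary are filtered first, then PCR
duplicates (identical coordinate tuples over all segments) are collapsed to
one representative, then gapped reads are split into splice-derived
(discarded) and structural (retained) by exact comparison against the
annotated-intron set.  Every retained chimera gets its arms assigned to
genes and is labelled intra / inter / unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation, IntronSet

__all__ = [
    "Arm",
    "ChimeraRecord",
    "FragmentIndex",
    "ExtractionResult",
    "extract_chimeras",
    "classify_gapped",
    "chimeras_to_tsv",
    "chimeras_to_bedpe",
    "read_chimeras_tsv",
]

DEFAULT_MIN_MAPQ = 30
MIN_ARM_LENGTH = 15  # chimeric segments shorter than this are alignment noise

ORIGIN_CHIMERIC = "chimeric_alignment"
ORIGIN_GAP = "retained_gap"

SCOPE_INTRA = "intra"
SCOPE_INTER = "inter"
SCOPE_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Arm:
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad arm interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Arm") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ChimeraRecord:
    """One ligation event: a 5' arm and a 3' arm in read order."""

    read_id: str
    arm5: Arm
    arm3: Arm
    origin: str
    gene5: Optional[str] = None
    gene3: Optional[str] = None

    @property
    def scope(self) -> str:
        if self.gene5 is None or self.gene3 is None:
            return SCOPE_UNASSIGNED
        return SCOPE_INTRA if self.gene5 == self.gene3 else SCOPE_INTER


class FragmentIndex:
    """Interval index of retained fragments for arm-coverage queries.

    Coverage of an arm is the number of distinct fragments (non-chimeric
    reads plus chimera arms) with >=1 bp of aligned block overlapping the
    arm on the matching strand.
    """

    def __init__(self):
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.n_fragments = 0

    def add(self, contig: str, strand: str, blocks: Iterable[Tuple[int, int]]) -> int:
        uid = self.n_fragments
        self.n_fragments += 1
        tree = self._trees.setdefault((contig, strand), IntervalTree())
        for (s, e) in blocks:
            if e > s:
                tree[s:e] = uid
        return uid

    def count_overlapping(self, arm: Arm) -> int:
        tree = self._trees.get((arm.contig, arm.strand))
        if tree is None:
            return 0
        return len({iv.data for iv in tree.overlap(arm.start, arm.end)})


@dataclass
class ExtractionResult:
    chimeras: List[ChimeraRecord]
    coverage: FragmentIndex
    counts: Dict[str, int] = field(default_factory=dict)

    def by_scope(self, scope: str) -> List[ChimeraRecord]:
        return [c for c in self.chimeras if c.scope == scope]


# -- per-fragment representation ----------------------------------------

@dataclass
class _Segment:
    contig: str
    strand: str
    blocks: Tuple[Tuple[int, int], ...]
    mapq: int
    supplementary: bool
    mate_index: int

    @property
    def start(self):
        return self.blocks[0][0]

    @property
    def end(self):
        return self.blocks[-1][1]


def _segment_of(aln: pysam.AlignedSegment) -> _Segment:
    return _Segment(
        contig=aln.reference_name,
        strand="-" if aln.is_reverse else "+",
        blocks=tuple(aln.get_blocks()),
        mapq=aln.mapping_quality,
        supplementary=aln.is_supplementary,
        mate_index=1 if (aln.is_paired and aln.is_read2) else 0,
    )


def classify_gapped(
    contig: str, strand: str, gaps: Sequence[Tuple[int, int]], introns: IntronSet
) -> str:
    """'splice' iff EVERY gap exactly equals an annotated intron, else 'structural'."""
    if not gaps:
        raise ValueError("classify_gapped requires at least one gap")
    for (s, e) in gaps:
        if (contig, strand, s, e) not in introns:
            return "structural"
    return "splice"


def _gaps(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    return [
        (e0, s1) for (_, e0), (s1, _) in zip(blocks, blocks[1:]) if s1 > e0
    ]


def _merge_mates(segs: List[_Segment]) -> List[_Segment]:
    """Treat a read pair as one fragment.

    Mates on the same contig and strand merge into a single block list;
    mates on different contigs (or strands) stay as two chimeric segments.
    """
    primaries = [s for s in segs if not s.supplementary]
    if len(primaries) < 2:
        return segs
    supp = [s for s in segs if s.supplementary]
    a, b = sorted(primaries[:2], key=lambda s: (s.contig, s.start))
    if a.contig == b.contig and a.strand == b.strand:
        blocks = sorted(set(a.blocks) | set(b.blocks))
        merged: List[Tuple[int, int]] = []
        for (s, e) in blocks:  # coalesce overlapping mate blocks
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        one = _Segment(a.contig, a.strand, tuple(merged), min(a.mapq, b.mapq), False, 0)
        return [one] + supp
    a2 = _Segment(b.contig, b.strand, b.blocks, b.mapq, True, b.mate_index)
    return [a, a2] + supp


def extract_chimeras(
    sam_path: str,
    ann: GenomeAnnotation,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_contigs: Sequence[str] = (),
    introns: Optional[IntronSet] = None,
) -> ExtractionResult:
    """Run the full extraction: filter, deduplicate, classify, assemble.

    Returns the chimera stream plus a fragment index over everything
    retained (for downstream coverage) and stage counts.
    """
    if introns is None:
        introns = ann.intron_set()
    excluded = set(exclude_contigs)

    fragments: Dict[str, List[_Segment]] = {}
    counts = {
        "alignments": 0,
        "secondary_dropped": 0,
        "excluded_contig": 0,
        "low_mapq_dropped": 0,
        "duplicates_removed": 0,
        "splice_gapped_discarded": 0,
        "multi_segment_skipped": 0,
        "nonchimeric": 0,
        "chimeras": 0,
        "intra": 0,
        "inter": 0,
        "unassigned": 0,
    }

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            counts["alignments"] += 1
            if aln.is_unmapped:
                continue
            if aln.is_secondary:
                counts["secondary_dropped"] += 1
                continue
            if aln.reference_name in excluded:
                counts["excluded_contig"] += 1
                continue
            fragments.setdefault(aln.query_name, []).append(_segment_of(aln))

    # MAPQ filter: a chimera survives only if every segment passes.
    passing: Dict[str, List[_Segment]] = {}
    for rid, segs in fragments.items():
        if any(s.mapq < min_mapq for s in segs):
            counts["low_mapq_dropped"] += 1
            continue
        passing[rid] = _merge_mates(segs) if len(
            [s for s in segs if not s.supplementary]
        ) > 1 else segs

    # Deduplicate on the full coordinate tuple over all segments.
    def dedup_key(segs: List[_Segment]):
        return tuple(
            sorted((s.contig, s.strand, s.blocks) for s in segs)
        )

    best: Dict[tuple, str] = {}
    for rid in sorted(passing):
        key = dedup_key(passing[rid])
        if key not in best:
            best[key] = rid
        else:
            counts["duplicates_removed"] += 1
    retained = {rid: passing[rid] for rid in best.values()}

    coverage = FragmentIndex()
    chimeras: List[ChimeraRecord] = []

    def finish(read_id: str, arm5: Arm, arm3: Arm, origin: str):
        gene5 = ann.assign_gene(arm5.contig, arm5.start, arm5.end, arm5.strand)
        gene3 = ann.assign_gene(arm3.contig, arm3.start, arm3.end, arm3.strand)
        rec = ChimeraRecord(read_id, arm5, arm3, origin, gene5, gene3)
        chimeras.append(rec)
        counts["chimeras"] += 1
        counts[rec.scope] += 1
        coverage.add(arm5.contig, arm5.strand, [(arm5.start, arm5.end)])
        coverage.add(arm3.contig, arm3.strand, [(arm3.start, arm3.end)])

    for rid in sorted(retained):
        segs = retained[rid]
        if len(segs) == 1:
            seg = segs[0]
            gaps = _gaps(seg.blocks)
            if not gaps:
                counts["nonchimeric"] += 1
                coverage.add(seg.contig, seg.strand, seg.blocks)
                continue
            kind = classify_gapped(seg.contig, seg.strand, gaps, introns)
            if kind == "splice":
                counts["splice_gapped_discarded"] += 1
                coverage.add(seg.contig, seg.strand, seg.blocks)
                continue
            # structural gap: arms are the merged blocks either side of the
            # largest gap
            big = max(gaps, key=lambda g: g[1] - g[0])
            left = [b for b in seg.blocks if b[1] <= big[0]]
            right = [b for b in seg.blocks if b[0] >= big[1]]
            arm5 = Arm(seg.contig, left[0][0], left[-1][1], seg.strand)
            arm3 = Arm(seg.contig, right[0][0], right[-1][1], seg.strand)
            if seg.strand == "-":  # read 5' end is the rightmost block
                arm5, arm3 = arm3, arm5
            finish(rid, arm5, arm3, ORIGIN_GAP)
        elif len(segs) == 2:
            prim = [s for s in segs if not s.supplementary]
            supp = [s for s in segs if s.supplementary]
            if len(prim) != 1 or len(supp) != 1:
                counts["multi_segment_skipped"] += 1
                continue
            p, q = prim[0], supp[0]
            arm5 = Arm(p.contig, p.start, p.end, p.strand)
            arm3 = Arm(q.contig, q.start, q.end, q.strand)
            finish(rid, arm5, arm3, ORIGIN_CHIMERIC)
        else:
            counts["multi_segment_skipped"] += 1

    if counts["multi_segment_skipped"]:
        warnings.warn(
            f"skipped {counts['multi_segment_skipped']} reads with !=2 chimeric segments",
            stacklevel=2,
        )
    return ExtractionResult(chimeras=chimeras, coverage=coverage, counts=counts)


# -- serialisation -------------------------------------------------------

_TSV_COLUMNS = [
    "read_id", "origin",
    "contig5", "start5", "end5", "strand5",
    "contig3", "start3", "end3", "strand3",
    "gene5", "gene3", "scope",
]


def chimeras_to_tsv(chimeras: Iterable[ChimeraRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in chimeras:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.read_id, c.origin,
                        c.arm5.contig, c.arm5.start, c.arm5.end, c.arm5.strand,
                        c.arm3.contig, c.arm3.start, c.arm3.end, c.arm3.strand,
                        c.gene5 or ".", c.gene3 or ".", c.scope,
                    )
                )
                + "\n"
            )


def read_chimeras_tsv(path: str) -> List[ChimeraRecord]:
    out: List[ChimeraRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError("unrecognised chimera TSV schema")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ChimeraRecord(
                    read_id=f[0],
                    origin=f[1],
                    arm5=Arm(f[2], int(f[3]), int(f[4]), f[5]),
                    arm3=Arm(f[6], int(f[7]), int(f[8]), f[9]),
                    gene5=None if f[10] == "." else f[10],
                    gene3=None if f[11] == "." else f[11],
                )
            )
    return out


def chimeras_to_bedpe(chimeras: Iterable[ChimeraRecord], path: str) -> None:
    with open(path, "w") as fh:
        for c in chimeras:
            fh.write(
                f"{c.arm5.contig}\t{c.arm5.start}\t{c.arm5.end}"
                f"\t{c.arm3.contig}\t{c.arm3.start}\t{c.arm3.end}"
                f"\t{c.read_id}\t.\t{c.arm5.strand}\t{c.arm3.strand}\n"
            )
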