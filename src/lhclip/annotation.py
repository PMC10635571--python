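"""Gene-annotation parsing, interval lookup and intron catalogues.

All coordinates are 0-based half-open internally.  GTF is read and written
as 1-based closed (the Ensembl dialect); the conversion happens only at the
file boundary.  The annotated-intron set produced here is what separates
splice-derived gapped reads (discarded) from structural gapped reads
(retained as chimeras) further down the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

__all__ = [
    "BIOTYPE_CLASSES",
    "AnnotationError",
    "GtfParseError",
    "GeneRecord",
    "TranscriptRecord",
    "GenomeAnnotation",
    "classify_biotype",
    "parse_gtf",
    "write_gtf",
    "read_contig_lengths",
]

#: The six biotype classes used for interaction-class accounting.
BIOTYPE_CLASSES = ("mRNA", "lncRNA", "snRNA", "snoRNA", "pseudogene", "other")

#: Raw GTF biotype -> class.  Anything not matched (incl. *_pseudogene
#: handled separately) falls through to "other".
_BIOTYPE_MAP: Dict[str, str] = {
    "protein_coding": "mRNA",
    "lincRNA": "lncRNA",
    "lncRNA": "lncRNA",
    "antisense": "lncRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "pseudogene": "pseudogene",
}


class AnnotationError(ValueError):
    """Invalid annotation content (coordinates, lookups)."""


class GtfParseError(AnnotationError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"GTF line {line_no}: {message}")
        self.line_no = line_no


def classify_biotype(biotype: str, mapping: Optional[Mapping[str, str]] = None) -> str:
    """Map a raw gene_biotype/gene_type string to one of BIOTYPE_CLASSES.

    The mapping is total: unknown biotypes become ``other`` and any
    ``*_pseudogene`` variant becomes ``pseudogene``.
    """
    table = _BIOTYPE_MAP if mapping is None else mapping
    if biotype in table:
        return table[biotype]
    if biotype.endswith("_pseudogene"):
        return "pseudogene"
    return "other"


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    biotype_class: str
    biotype: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype_class not in BIOTYPE_CLASSES:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown biotype class {self.biotype_class!r}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]  # sorted, non-overlapping, half-open

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s, e) in exons:
            if not 0 <= s < e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: bad exon ({s}, {e})"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Exon-adjacent gaps, i.e. the complement of exons within the span."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )


class IntronSet:
    """Deduplicated annotated introns keyed by (contig, strand).

    Membership is exact: a gap matches only if its (donor, acceptor)
    coordinates equal an annotated intron on the same contig and strand.
    """

    def __init__(self, by_key: Mapping[Tuple[str, str], Iterable[Tuple[int, int]]]):
        self._by_key: Dict[Tuple[str, str], frozenset] = {
            k: frozenset(tuple(iv) for iv in v) for k, v in by_key.items()
        }

    def __contains__(self, item: Tuple[str, str, int, int]) -> bool:
        contig, strand, start, end = item
        return (start, end) in self._by_key.get((contig, strand), frozenset())

    def intervals(self, contig: str, strand: str) -> List[Tuple[int, int]]:
        return sorted(self._by_key.get((contig, strand), frozenset()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_key.values())


class GenomeAnnotation:
    """Genes + transcripts with an interval index for arm-to-gene assignment."""

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        transcripts: Sequence[TranscriptRecord],
        contigs: Sequence[Tuple[str, int]],
    ):
        self.genes: List[GeneRecord] = list(genes)
        self.transcripts: List[TranscriptRecord] = list(transcripts)
        self.contigs: List[Tuple[str, int]] = [(str(c), int(n)) for c, n in contigs]
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        if len(self._gene_by_id) != len(self.genes):
            raise AnnotationError("duplicate gene_id in annotation")
        self._contig_lengths = dict(self.contigs)
        known = set(self._contig_lengths)
        for g in self.genes:
            if g.contig not in known:
                raise AnnotationError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > self._contig_lengths[g.contig]:
                raise AnnotationError(f"gene {g.gene_id} beyond contig end")
        for t in self.transcripts:
            gene = self._gene_by_id.get(t.gene_id)
            if gene is None:
                raise AnnotationError(f"transcript {t.transcript_id}: unknown gene")
            if t.contig != gene.contig or t.strand != gene.strand:
                raise AnnotationError(
                    f"transcript {t.transcript_id}: contig/strand mismatch with gene"
                )
            if t.start < gene.start or t.end > gene.end:
                raise AnnotationError(
                    f"transcript {t.transcript_id}: exon outside gene span"
                )
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.contig, IntervalTree())[g.start : g.end] = g

    # -- lookups ---------------------------------------------------------

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_by_id[gene_id]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_by_id

    def contig_length(self, contig: str) -> int:
        try:
            return self._contig_lengths[contig]
        except KeyError:
            raise AnnotationError(f"unknown contig {contig!r}") from None

    def transcripts_of(self, gene_id: str) -> List[TranscriptRecord]:
        return [t for t in self.transcripts if t.gene_id == gene_id]

    def assign_gene(
        self, contig: str, start: int, end: int, strand: str
    ) -> Optional[str]:
        """Assign a genomic arm to a gene by its midpoint.

        The gene whose span contains the arm midpoint on the matching strand
        wins; nested-gene ties break to the smaller span, then the
        lexicographically smaller gene_id.  Returns None for intergenic arms.
        """
        if contig not in self._contig_lengths:
            raise AnnotationError(f"unknown contig {contig!r}")
        tree = self._trees.get(contig)
        if tree is None:
            return None
        mid = (start + end) // 2
        hits = [iv.data for iv in tree.at(mid) if iv.data.strand == strand]
        if not hits:
            return None
        best = min(hits, key=lambda g: (g.span, g.gene_id))
        return best.gene_id

    def biotype_class_of(self, gene_id: str) -> str:
        return self._gene_by_id[gene_id].biotype_class

    def intron_set(self) -> IntronSet:
        by_key: Dict[Tuple[str, str], set] = {}
        for t in self.transcripts:
            for intron in t.introns:
                by_key.setdefault((t.contig, t.strand), set()).add(intron)
        return IntronSet(by_key)


# -- GTF I/O -------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field8: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field8))


def parse_gtf(
    path: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
    biotype_map: Optional[Mapping[str, str]] = None,
) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a GenomeAnnotation.

    Requires gene/transcript/exon features with ``gene_id``,
    ``transcript_id`` and ``gene_biotype`` (or ``gene_type``) attributes.
    When ``contig_lengths`` is omitted, each contig's length is taken as the
    rightmost annotated coordinate.
    """
    genes: Dict[str, GeneRecord] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    tx_meta: Dict[str, Tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)
    max_coord: Dict[str, int] = {}

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"expected 9 fields, got {len(fields)}", line_no)
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError("non-integer coordinates", line_no) from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"bad coordinates {start1}-{end1}", line_no)
            start, end = start1 - 1, end1  # to 0-based half-open
            max_coord[contig] = max(max_coord.get(contig, 0), end)
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError("missing gene_id attribute", line_no)
            if feature == "gene":
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                genes[gene_id] = GeneRecord(
                    gene_id=gene_id,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype_class=classify_biotype(biotype, biotype_map),
                    biotype=biotype,
                )
            elif feature == "exon":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError("exon without transcript_id", line_no)
                exons.setdefault(tx_id, []).append((start, end))
                tx_meta.setdefault(tx_id, (gene_id, contig, strand))
            elif feature == "transcript":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError("transcript without transcript_id", line_no)
                tx_meta.setdefault(tx_id, (gene_id, contig, strand))

    transcripts = [
        TranscriptRecord(
            transcript_id=tx_id,
            gene_id=meta[0],
            contig=meta[1],
            strand=meta[2],
            exons=tuple(sorted(exons.get(tx_id, []))),
        )
        for tx_id, meta in tx_meta.items()
        if exons.get(tx_id)
    ]
    if contig_lengths is None:
        contigs = sorted(max_coord.items())
    else:
        contigs = sorted(contig_lengths.items())
    return GenomeAnnotation(
        genes=list(genes.values()), transcripts=transcripts, contigs=contigs
    )


def write_gtf(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation back out as Ensembl-dialect GTF (1-based closed)."""
    tx_by_gene: Dict[str, List[TranscriptRecord]] = {}
    for t in ann.transcripts:
        tx_by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        for g in sorted(ann.genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype or g.biotype_class}";'
            fh.write(
                f"{g.contig}\tlhclip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in sorted(tx_by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
                tattrs = attrs[:-1] + f' transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.contig}\tlhclip\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for (s, e) in t.exons:
                    fh.write(
                        f"{g.contig}\tlhclip\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def read_contig_lengths(path: str) -> Dict[str, int]:
    """Read contig lengths from a 2-column TSV (name, length)."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            out[name] = int(length)
    return out
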