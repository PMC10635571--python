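"""Alternative-splicing events and their ncRNA-binding annotation.

Events come from a MISO-style summary table and are filtered with the
standard significance thresholds (inclusion/exclusion read support, |dPsi|,
Bayes factor).  An event counts as bound with an ncRNA when at least one
significant intermolecular interaction arm overlaps an exon or intron part
of the event (the arm assigned to the event's host gene) and the partner
arm's gene belongs to an ncRNA class.  For unbound events the nearest
ncRNA-partnered arm is reported with its distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation import GenomeAnnotation
from .extract import Arm, ChimeraRecord, SCOPE_INTER

__all__ = [
    "MisoFilters",
    "SplicingEvent",
    "BoundEventAnnotation",
    "load_events",
    "annotate_bound_events",
    "summarize_bound",
    "write_annotations_tsv",
]

EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "MXE")

#: Partner biotype classes that count as ncRNA binders.
DEFAULT_NCRNA_CLASSES = frozenset({"lncRNA", "snRNA", "snoRNA"})


@dataclass(frozen=True)
class MisoFilters:
    """Significance thresholds, all inclusive (>=)."""

    min_inc: int = 1
    min_exc: int = 1
    min_sum_inc_exc: int = 10
    min_abs_delta_psi: float = 0.20
    min_bayes_factor: float = 10.0

    def passes(self, n_inc: int, n_exc: int, delta_psi: float, bayes_factor: float) -> bool:
        return (
            n_inc >= self.min_inc
            and n_exc >= self.min_exc
            and (n_inc + n_exc) >= self.min_sum_inc_exc
            and abs(delta_psi) >= self.min_abs_delta_psi
            and bayes_factor >= self.min_bayes_factor
        )


@dataclass(frozen=True)
class SplicingEvent:
    event_id: str
    event_type: str
    gene_id: str
    contig: str
    strand: str
    parts: Tuple[Tuple[str, int, int], ...]  # (label exon|intron, start, end)
    n_inc: int
    n_exc: int
    delta_psi: float
    bayes_factor: float

    def __post_init__(self):
        if not self.parts:
            raise ValueError(f"event {self.event_id}: no parts")
        for label, s, e in self.parts:
            if label not in ("exon", "intron"):
                raise ValueError(f"event {self.event_id}: bad part label {label!r}")
            if not 0 <= s < e:
                raise ValueError(f"event {self.event_id}: bad part interval")

    @property
    def span(self) -> Tuple[int, int]:
        return (min(s for _, s, _ in self.parts), max(e for _, _, e in self.parts))


@dataclass
class BoundEventAnnotation:
    event_id: str
    bound: bool
    # (ncRNA gene_id, biotype class, overlapped part label, partner arm)
    binding_ncrnas: List[Tuple[str, str, str, Arm]] = field(default_factory=list)
    nearest_ncrna: Optional[str] = None
    nearest_distance: Optional[int] = None


_REQUIRED_COLUMNS = [
    "event_id", "event_type", "gene_id", "contig", "strand", "parts",
    "n_inc", "n_exc", "delta_psi", "bayes_factor",
]


def _parse_parts(text: str) -> Tuple[Tuple[str, int, int], ...]:
    # "exon:100-200;intron:200-350" with 0-based half-open coordinates
    parts = []
    for token in text.split(";"):
        label, rng = token.split(":")
        s, e = rng.split("-")
        parts.append((label.strip(), int(s), int(e)))
    return tuple(parts)


def load_events(path: str, filters: Optional[MisoFilters] = None) -> List[SplicingEvent]:
    """Load a MISO-style summary TSV and keep events passing the filters.

    Pass ``filters=None`` for the defaults; a falsy-free way to disable
    filtering is ``MisoFilters(0, 0, 0, 0.0, 0.0)``.
    """
    if filters is None:
        filters = MisoFilters()
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    events: List[SplicingEvent] = []
    for row in df.itertuples():
        ev = SplicingEvent(
            event_id=str(row.event_id),
            event_type=str(row.event_type),
            gene_id=str(row.gene_id),
            contig=str(row.contig),
            strand=str(row.strand),
            parts=_parse_parts(str(row.parts)),
            n_inc=int(row.n_inc),
            n_exc=int(row.n_exc),
            delta_psi=float(row.delta_psi),
            bayes_factor=float(row.bayes_factor),
        )
        if filters.passes(ev.n_inc, ev.n_exc, ev.delta_psi, ev.bayes_factor):
            events.append(ev)
    return events


def _distance(arm: Arm, span: Tuple[int, int]) -> int:
    if arm.end <= span[0]:
        return span[0] - arm.end
    if arm.start >= span[1]:
        return arm.start - span[1]
    return 0


def annotate_bound_events(
    events: Sequence[SplicingEvent],
    interactions: Sequence[ChimeraRecord],
    ann: GenomeAnnotation,
    ncrna_classes: Iterable[str] = DEFAULT_NCRNA_CLASSES,
    require_host_gene: bool = True,
) -> List[BoundEventAnnotation]:
    """Mark events bound by ncRNA interaction arms.

    ``interactions`` should be the significant intermolecular chimeras.  An
    event is bound iff some arm overlaps (>=1 bp) one of its exon/intron
    parts, that arm's assigned gene equals the event's host gene (when
    ``require_host_gene``), and the partner arm's gene is in an ncRNA class.
    """
    ncrna_classes = frozenset(ncrna_classes)

    # (event-side arm, its gene, partner gene, partner class, partner arm)
    arm_pairs: List[Tuple[Arm, str, str, str, Arm]] = []
    for c in interactions:
        if c.scope != SCOPE_INTER:
            continue
        for ev_arm, ev_gene, partner_gene, partner_arm in (
            (c.arm5, c.gene5, c.gene3, c.arm3),
            (c.arm3, c.gene3, c.gene5, c.arm5),
        ):
            cls = ann.biotype_class_of(partner_gene)
            if cls in ncrna_classes:
                arm_pairs.append((ev_arm, ev_gene, partner_gene, cls, partner_arm))

    out: List[BoundEventAnnotation] = []
    for ev in events:
        binders: List[Tuple[str, str, str, Arm]] = []
        nearest: Optional[Tuple[int, str]] = None
        for ev_arm, ev_gene, partner_gene, cls, partner_arm in arm_pairs:
            if ev_arm.contig != ev.contig or ev_arm.strand != ev.strand:
                continue
            if require_host_gene and ev_gene != ev.gene_id:
                continue
            hit_part = None
            for label, s, e in ev.parts:
                if ev_arm.start < e and s < ev_arm.end:
                    hit_part = label
                    break
            if hit_part is not None:
                binders.append((partner_gene, cls, hit_part, partner_arm))
            else:
                d = _distance(ev_arm, ev.span)
                if nearest is None or (d, partner_gene) < nearest:
                    nearest = (d, partner_gene)
        rec = BoundEventAnnotation(event_id=ev.event_id, bound=bool(binders),
                                   binding_ncrnas=binders)
        if not binders and nearest is not None:
            rec.nearest_distance, rec.nearest_ncrna = nearest
        out.append(rec)
    return out


def summarize_bound(annotations: Sequence[BoundEventAnnotation]) -> Dict[str, int]:
    """Event counts bound per partner class (event counted once per class),
    plus 'any_ncRNA' and 'unbound' totals."""
    summary: Dict[str, int] = {"any_ncRNA": 0, "unbound": 0}
    for rec in annotations:
        if not rec.bound:
            summary["unbound"] += 1
            continue
        summary["any_ncRNA"] += 1
        for cls in {cls for _, cls, _, _ in rec.binding_ncrnas}:
            summary[cls] = summary.get(cls, 0) + 1
    return summary


def write_annotations_tsv(annotations: Sequence[BoundEventAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tbound\tbinding_ncRNAs\tnearest_ncRNA\tnearest_distance\n")
        for rec in annotations:
            binders = ",".join(
                f"{g}({cls}@{part})" for g, cls, part, _ in rec.binding_ncrnas
            )
            fh.write(
                f"{rec.event_id}\t{int(rec.bound)}\t{binders or '.'}"
                f"\t{rec.nearest_ncrna or '.'}"
                f"\t{rec.nearest_distance if rec.nearest_distance is not None else '.'}\n"
            )
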