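"""Duplex-group (DG) calling for intramolecular chimeras.

Chimeras from the same gene whose left arms mutually overlap AND whose
right arms mutually overlap are clustered into duplex groups (connected
components of the both-arm-overlap graph).  A group is reported only with
at least two unique chimeric reads with different termini, and scored with
the connection score

    score = coverage_AB / sqrt(coverage_A * coverage_B)

where coverage_AB is the number of supporting chimeras and coverage_A/B
count fragments overlapping each consensus arm.  Groups are kept when the
score is strictly greater than the cutoff (default 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .extract import Arm, ChimeraRecord, FragmentIndex, SCOPE_INTRA

__all__ = [
    "DuplexGroup",
    "connection_score",
    "cluster_duplex_groups",
    "compute_arm_coverage",
    "score_groups",
    "filter_groups",
    "call_duplex_groups",
    "groups_to_tsv",
    "groups_to_bed12",
]

DEFAULT_SCORE_CUTOFF = 0.01


@dataclass
class DuplexGroup:
    gene_id: str
    arm_a: Arm  # leftmost consensus arm (union of member arms)
    arm_b: Arm
    member_ids: Tuple[str, ...]
    n_unique_termini: int
    coverage_a: float = 0.0
    coverage_b: float = 0.0
    coverage_ab: float = 0.0
    score: float = 0.0

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def connection_score(coverage_ab: float, coverage_a: float, coverage_b: float) -> float:
    """coverage_AB / sqrt(coverage_A * coverage_B); 0 if either coverage is 0."""
    if min(coverage_ab, coverage_a, coverage_b) < 0:
        raise ValueError("coverages must be non-negative")
    if coverage_a == 0 or coverage_b == 0:
        return 0.0
    return coverage_ab / math.sqrt(coverage_a * coverage_b)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _normalized_arms(c: ChimeraRecord) -> Optional[Tuple[Arm, Arm]]:
    """Arms in genomic order (A = leftmost); None for overlapping-arm artifacts."""
    a, b = sorted((c.arm5, c.arm3), key=lambda arm: (arm.start, arm.end))
    if b.start < a.end:  # arms overlap each other: circular/artifactual
        return None
    return a, b


def cluster_duplex_groups(intra_chimeras: Sequence[ChimeraRecord]) -> List[DuplexGroup]:
    """Connected components of the both-arm-overlap graph, per gene.

    Within each gene, chimeras are sorted by left-arm start; a sweep
    enumerates exactly the pairs whose left arms overlap, and an edge is
    added when the right arms overlap too.  Groups whose members do not
    include two distinct terminus 4-tuples are dropped.
    """
    by_gene: Dict[str, List[Tuple[ChimeraRecord, Arm, Arm]]] = {}
    for c in intra_chimeras:
        if c.scope != SCOPE_INTRA:
            raise ValueError(f"chimera {c.read_id} is not intramolecular")
        arms = _normalized_arms(c)
        if arms is None:
            continue
        by_gene.setdefault(c.gene5, []).append((c, arms[0], arms[1]))

    groups: List[DuplexGroup] = []
    for gene_id in sorted(by_gene):
        items = sorted(by_gene[gene_id], key=lambda t: (t[1].start, t[1].end))
        n = len(items)
        uf = _UnionFind(n)
        for i in range(n):
            _, ai, bi = items[i]
            for j in range(i + 1, n):
                _, aj, bj = items[j]
                if aj.start >= ai.end:  # sorted by start: no further A-overlap
                    break
                if bj.start < bi.end and bi.start < bj.end:
                    uf.union(i, j)
        comps: Dict[int, List[int]] = {}
        for i in range(n):
            comps.setdefault(uf.find(i), []).append(i)
        for members in comps.values():
            termini = {
                (items[i][1].start, items[i][1].end, items[i][2].start, items[i][2].end)
                for i in members
            }
            if len(termini) < 2:
                continue
            arms_a = [items[i][1] for i in members]
            arms_b = [items[i][2] for i in members]
            contig = arms_a[0].contig
            strand = arms_a[0].strand
            arm_a = Arm(contig, min(a.start for a in arms_a), max(a.end for a in arms_a), strand)
            arm_b = Arm(contig, min(b.start for b in arms_b), max(b.end for b in arms_b), strand)
            groups.append(
                DuplexGroup(
                    gene_id=gene_id,
                    arm_a=arm_a,
                    arm_b=arm_b,
                    member_ids=tuple(sorted(items[i][0].read_id for i in members)),
                    n_unique_termini=len(termini),
                )
            )
    return groups


def compute_arm_coverage(arm: Arm, coverage: FragmentIndex) -> float:
    """Fragments (non-chimeric reads + chimera arms) overlapping the arm >=1 bp."""
    return float(coverage.count_overlapping(arm))


def score_groups(groups: Iterable[DuplexGroup], coverage: FragmentIndex) -> List[DuplexGroup]:
    out = []
    for g in groups:
        g.coverage_ab = float(g.n_members)
        g.coverage_a = compute_arm_coverage(g.arm_a, coverage)
        g.coverage_b = compute_arm_coverage(g.arm_b, coverage)
        g.score = connection_score(g.coverage_ab, g.coverage_a, g.coverage_b)
        out.append(g)
    return out


def filter_groups(
    groups: Iterable[DuplexGroup], cutoff: float = DEFAULT_SCORE_CUTOFF
) -> List[DuplexGroup]:
    """Keep groups with score strictly greater than the cutoff."""
    return [g for g in groups if g.score > cutoff]


def call_duplex_groups(
    intra_chimeras: Sequence[ChimeraRecord],
    coverage: FragmentIndex,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> List[DuplexGroup]:
    """Cluster, score and filter in one step."""
    return filter_groups(score_groups(cluster_duplex_groups(intra_chimeras), coverage), cutoff)


# -- serialisation -------------------------------------------------------

def groups_to_tsv(groups: Iterable[DuplexGroup], path: str) -> None:
    cols = [
        "gene_id", "contig", "strand",
        "armA_start", "armA_end", "armB_start", "armB_end",
        "n_members", "n_unique_termini",
        "coverage_A", "coverage_B", "coverage_AB", "score",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in groups:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.gene_id, g.arm_a.contig, g.arm_a.strand,
                        g.arm_a.start, g.arm_a.end, g.arm_b.start, g.arm_b.end,
                        g.n_members, g.n_unique_termini,
                        g.coverage_a, g.coverage_b, g.coverage_ab,
                        f"{g.score:.6g}",
                    )
                )
                + "\n"
            )


def groups_to_bed12(groups: Iterable[DuplexGroup], path: str) -> None:
    """BED12 arcs: one record per group, two blocks = the two arms."""
    with open(path, "w") as fh:
        for i, g in enumerate(groups):
            chrom_start = g.arm_a.start
            chrom_end = g.arm_b.end
            sizes = f"{g.arm_a.length},{g.arm_b.length}"
            starts = f"0,{g.arm_b.start - chrom_start}"
            fh.write(
                f"{g.arm_a.contig}\t{chrom_start}\t{chrom_end}\tDG{i:05d}_{g.gene_id}"
                f"\t{min(int(g.score * 1000), 1000)}\t{g.arm_a.strand}"
                f"\t{chrom_start}\t{chrom_end}\t0\t2\t{sizes}\t{starts}\n"
            )
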