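"""Contact-map export and interaction summaries.

Writes chimeric contacts in Juicer's ``.short`` text format (8
whitespace-separated fields per row: str chr pos frag, twice), computes
the distribution of intermolecular interactions across RNA biotype
classes, builds gene-list contact-count heatmap matrices (displayed as
log10 counts), and compares two interaction-site sets with an upper-tail
hypergeometric test.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import GenomeAnnotation
from .extract import ChimeraRecord, SCOPE_INTER

__all__ = [
    "ContactRecord",
    "write_short_format",
    "parse_short_format",
    "class_distribution",
    "pair_heatmap_counts",
    "log10_display",
    "interaction_set_overlap",
]

_STRAND_CODE = {"+": 0, "-": 1}
_CODE_STRAND = {0: "+", 1: "-"}

# One .short row: str1 chr1 pos1 frag1 str2 chr2 pos2 frag2
ContactRecord = Tuple[int, str, int, int, int, str, int, int]


def _contact_of(c: ChimeraRecord) -> ContactRecord:
    """Order the two arms so (chr1, pos1) <= (chr2, pos2); pos is the
    5'-most aligned base, 1-based."""
    sides = []
    for arm in (c.arm5, c.arm3):
        pos = arm.start + 1 if arm.strand == "+" else arm.end  # 5'-most base
        sides.append((arm.contig, pos, _STRAND_CODE[arm.strand]))
    (c1, p1, s1), (c2, p2, s2) = sorted(sides)
    return (s1, c1, p1, 0, s2, c2, p2, 1)


def write_short_format(chimeras: Sequence[ChimeraRecord], path: str,
                       ann: Optional[GenomeAnnotation] = None) -> None:
    """Write contacts as Juicer `pre` input, sorted by chr1 then chr2."""
    known = {c for c, _ in ann.contigs} if ann is not None else None
    rows: List[ContactRecord] = []
    for c in chimeras:
        if known is not None and (c.arm5.contig not in known or c.arm3.contig not in known):
            raise ValueError(f"chimera {c.read_id} on unknown contig")
        rows.append(_contact_of(c))
    rows.sort(key=lambda r: (r[1], r[5], r[2], r[6]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(" ".join(str(x) for x in r) + "\n")


def parse_short_format(path: str) -> List[ContactRecord]:
    """Strict re-parser for the 8-field .short grammar."""
    out: List[ContactRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if len(f) != 8:
                raise ValueError(f".short line {ln}: expected 8 fields, got {len(f)}")
            s1, c1, p1, f1, s2, c2, p2, f2 = f
            for name, v in (("str1", s1), ("str2", s2)):
                if v not in ("0", "1"):
                    raise ValueError(f".short line {ln}: {name} must be 0/1")
            p1i, p2i, f1i, f2i = int(p1), int(p2), int(f1), int(f2)
            if p1i < 1 or p2i < 1:
                raise ValueError(f".short line {ln}: positions are 1-based")
            if (c1, p1i) > (c2, p2i):
                raise ValueError(f".short line {ln}: sides not coordinate-ordered")
            out.append((int(s1), c1, p1i, f1i, int(s2), c2, p2i, f2i))
    for a, b in zip(out, out[1:]):
        if (a[1], a[5]) > (b[1], b[5]):
            raise ValueError(".short file not sorted by chromosome names")
    return out


def class_distribution(
    inter_chimeras: Sequence[ChimeraRecord], ann: GenomeAnnotation
) -> pd.DataFrame:
    """Unordered biotype-class pair counts and fractions over assigned pairs.

    Fractions sum to 1; the total count conserves the number of
    class-assigned intermolecular chimeras.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for c in inter_chimeras:
        if c.scope != SCOPE_INTER:
            continue
        cls = tuple(sorted((ann.biotype_class_of(c.gene5), ann.biotype_class_of(c.gene3))))
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    rows = [
        {"class_pair": f"{a}-{b}", "count": n, "fraction": n / total if total else 0.0}
        for (a, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["class_pair", "count", "fraction"])


def pair_heatmap_counts(
    gene_list_a: Sequence[str],
    gene_list_b: Sequence[str],
    pair_table: pd.DataFrame,
) -> pd.DataFrame:
    """Contact-count matrix M[i, j] = n_contacts(a_i, b_j); 0 where untested."""
    for name, lst in (("gene_list_a", gene_list_a), ("gene_list_b", gene_list_b)):
        if not len(lst):
            raise ValueError(f"{name} is empty")
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate gene in {name}")
    lookup: Dict[Tuple[str, str], int] = {
        (r.gene_a, r.gene_b): int(r.n_contacts) for r in pair_table.itertuples()
    }
    mat = np.zeros((len(gene_list_a), len(gene_list_b)), dtype=int)
    for i, ga in enumerate(gene_list_a):
        for j, gb in enumerate(gene_list_b):
            a, b = sorted((ga, gb))
            mat[i, j] = lookup.get((a, b), 0)
    return pd.DataFrame(mat, index=list(gene_list_a), columns=list(gene_list_b))


def log10_display(counts: pd.DataFrame) -> pd.DataFrame:
    """log10 transform for heatmap display; zero counts are masked (NaN)."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log10(arr)
    out[~(arr > 0)] = np.nan
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def _midpoint_match(
    sites_a: Sequence[Tuple[str, int, int]],
    sites_b: Sequence[Tuple[str, int, int]],
) -> int:
    """Sites in A whose midpoint falls inside some B interval (>=1 bp rule)."""
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for (c, s, e) in sites_b:
        by_contig.setdefault(c, []).append((s, e))
    n = 0
    for (c, s, e) in sites_a:
        mid = (s + e) // 2
        if any(bs <= mid < be for (bs, be) in by_contig.get(c, ())):
            n += 1
    return n


def interaction_set_overlap(
    sites_a: Sequence[Tuple[str, int, int]],
    sites_b: Sequence[Tuple[str, int, int]],
    universe_size: int,
) -> Tuple[int, float]:
    """Overlap count between two interaction-site sets and its hypergeometric P.

    Sites match when one set's interval midpoint lies within the other's
    interval.  P is the upper tail of Hypergeom(N=universe, K=|B|, n=|A|)
    at >= n_overlap draws.
    """
    if universe_size < max(len(sites_a), len(sites_b)):
        raise ValueError("universe smaller than one of the sets")
    n_overlap = _midpoint_match(sites_a, sites_b)
    p = float(hypergeom.sf(n_overlap - 1, universe_size, len(sites_b), len(sites_a)))
    return n_overlap, p
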