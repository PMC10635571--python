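"""Shared fixtures: a handcrafted annotation and seeded simulator bundles."""

import numpy as np
import pytest

from lhclip.annotation import GeneRecord, GenomeAnnotation, TranscriptRecord
from lhclip.extract import extract_chimeras
from lhclip.simulate import (
    SimConfig,
    plant_duplexes,
    simulate_annotation,
    simulate_reads,
    write_sam,
)


def make_toy_annotation():
    """Two-gene-plus-nested toy genome on chr1 for deterministic unit tests.

    GA (mRNA, +) has 3 exons and 2 introns; GNEST (snoRNA, +) sits inside
    GA's middle intron region; GB (lncRNA, -) has 2 exons; GC (snRNA, +) is
    single-exon.
    """
    genes = [
        GeneRecord("GA", "chr1", 1000, 2200, "+", "mRNA", "protein_coding"),
        GeneRecord("GNEST", "chr1", 1250, 1450, "+", "snoRNA", "snoRNA"),
        GeneRecord("GB", "chr1", 3000, 4000, "-", "lncRNA", "lincRNA"),
        GeneRecord("GC", "chr1", 5000, 5200, "+", "snRNA", "snRNA"),
    ]
    transcripts = [
        TranscriptRecord("GA.t1", "GA", "chr1", "+",
                         ((1000, 1200), (1500, 1700), (2000, 2200))),
        TranscriptRecord("GNEST.t1", "GNEST", "chr1", "+", ((1250, 1450),)),
        TranscriptRecord("GB.t1", "GB", "chr1", "-", ((3000, 3300), (3600, 4000))),
        TranscriptRecord("GC.t1", "GC", "chr1", "+", ((5000, 5200),)),
    ]
    return GenomeAnnotation(genes, transcripts, [("chr1", 100000)])


@pytest.fixture
def toy_ann():
    return make_toy_annotation()


def simulate_bundle(tmp_path, seed=3, n_duplexes=10, n_support=5, **cfg_kwargs):
    """Simulate annotation + reads + SAM on disk; return (cfg, ann, truth, result)."""
    defaults = dict(n_nonchimeric_reads=1500, n_splice_gapped_reads=150, seed=seed)
    defaults.update(cfg_kwargs)
    cfg = SimConfig(**defaults)
    ann = simulate_annotation(cfg)
    if n_duplexes:
        rng = np.random.default_rng(seed + 1000)
        cfg.planted_duplexes = plant_duplexes(ann, n_duplexes, n_support, rng)
    records, truth = simulate_reads(cfg, ann)
    sam = str(tmp_path / "reads.sam")
    write_sam(records, ann, sam)
    result = extract_chimeras(sam, ann)
    return cfg, ann, truth, result


@pytest.fixture
def sim_bundle(tmp_path):
    return simulate_bundle(tmp_path)


def build_58_event_fixture():
    """58 splicing events, one per host gene, with interaction arms planted
    so that exactly 1 event is snRNA-bound, 4 are lncRNA-bound and 53 are
    unbound (the structure of a small knockdown splicing screen)."""
    from lhclip.extract import Arm, ChimeraRecord
    from lhclip.splicing import SplicingEvent

    genes, events = [], []
    for i in range(58):
        base = 10000 * (i + 1)
        gid = f"HOST{i:02d}"
        genes.append(GeneRecord(gid, "chr1", base, base + 2000, "+", "mRNA"))
        events.append(
            SplicingEvent(
                f"ev{i:02d}", "SE", gid, "chr1", "+",
                (("exon", base + 100, base + 200),
                 ("intron", base + 200, base + 500),
                 ("exon", base + 500, base + 600)),
                n_inc=4, n_exc=8, delta_psi=0.30, bayes_factor=20.0,
            )
        )
    genes.append(GeneRecord("SNX", "chr1", 900000, 900200, "+", "snRNA"))
    genes.append(GeneRecord("LNCX", "chr1", 910000, 912000, "+", "lncRNA"))
    ann = GenomeAnnotation(genes, [], [("chr1", 1000000)])

    def arm_pair(i, partner, p_start):
        base = 10000 * (i + 1)
        return ChimeraRecord(
            f"arm{i:02d}_{partner}",
            Arm("chr1", base + 250, base + 280, "+"),   # inside the intron part
            Arm("chr1", p_start, p_start + 30, "+"),
            "chimeric_alignment",
            gene5=f"HOST{i:02d}",
            gene3=partner,
        )

    inters = [arm_pair(0, "SNX", 900050)]
    inters += [arm_pair(1 + k, "LNCX", 910100 + 40 * k) for k in range(4)]
    return ann, events, inters
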