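"""Chimeric-read extraction: filters, dedup, gap classification, assembly."""

import pytest

from lhclip.extract import (
    SCOPE_INTER,
    SCOPE_INTRA,
    chimeras_to_tsv,
    classify_gapped,
    extract_chimeras,
    read_chimeras_tsv,
)
from lhclip.simulate import CHIMERA_MECHANISMS
from conftest import simulate_bundle


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(qname, flag, pos1, mapq, cigar, extra=""):
    return (
        f"{qname}\t{flag}\tchr1\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*{extra}\n"
    )


def write_sam_text(tmp_path, body, name="t.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + body)
    return str(p)


class TestQualityFilter:
    @pytest.mark.parametrize("mapq,kept", [(29, 0), (30, 1), (60, 1)])
    def test_mapq_boundary_at_30(self, tmp_path, toy_ann, mapq, kept):
        sam = write_sam_text(tmp_path, sam_line("r1", 0, 1001, mapq, "50M"))
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["nonchimeric"] == kept

    def test_secondary_alignment_dropped_even_at_high_mapq(self, tmp_path, toy_ann):
        sam = write_sam_text(tmp_path, sam_line("r1", 256, 1001, 60, "50M"))
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["secondary_dropped"] == 1
        assert res.counts["nonchimeric"] == 0

    def test_chimera_dropped_if_one_segment_fails(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 0, 1001, 60, "30M", "\tSA:Z:chr1,3001,+,30M,10,0;")
            + sam_line("r1", 2048, 3001, 10, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["chimeras"] == 0
        assert res.counts["low_mapq_dropped"] == 1

    def test_contig_exclusion_list(self, tmp_path, toy_ann):
        sam = write_sam_text(tmp_path, sam_line("r1", 0, 1001, 60, "50M"))
        res = extract_chimeras(sam, toy_ann, exclude_contigs=["chr1"])
        assert res.counts["excluded_contig"] == 1
        assert res.counts["nonchimeric"] == 0


class TestDeduplicate:
    def test_identical_chimeras_keep_smallest_read_id(self, tmp_path, toy_ann):
        def chim(q):
            return (
                sam_line(q, 0, 1001, 60, "30M", "\tSA:Z:chr1,2001,+,30M,60,0;")
                + sam_line(q, 2048, 2001, 60, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
            )

        sam = write_sam_text(tmp_path, chim("r2") + chim("r1"))
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["duplicates_removed"] == 1
        assert [c.read_id for c in res.chimeras] == ["r1"]

    def test_one_bp_terminus_difference_keeps_both(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 0, 1001, 60, "30M", "\tSA:Z:chr1,2001,+,30M,60,0;")
            + sam_line("r1", 2048, 2001, 60, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
            + sam_line("r2", 0, 1002, 60, "30M", "\tSA:Z:chr1,2001,+,30M,60,0;")
            + sam_line("r2", 2048, 2001, 60, "30M", "\tSA:Z:chr1,1002,+,30M,60,0;")
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["chimeras"] == 2
        assert res.counts["duplicates_removed"] == 0


class TestClassifyGapped:
    def test_exact_intron_gap_is_splice(self, toy_ann):
        introns = toy_ann.intron_set()
        assert classify_gapped("chr1", "+", [(1200, 1500)], introns) == "splice"

    def test_shifted_donor_is_structural(self, toy_ann):
        introns = toy_ann.intron_set()
        assert classify_gapped("chr1", "+", [(1203, 1500)], introns) == "structural"

    def test_every_gap_must_be_intronic(self, toy_ann):
        introns = toy_ann.intron_set()
        gaps = [(1200, 1500), (1750, 1900)]  # second gap is not annotated
        assert classify_gapped("chr1", "+", gaps, introns) == "structural"
        assert classify_gapped("chr1", "+", [(1200, 1500), (1700, 2000)], introns) == "splice"

    def test_strand_matters(self, toy_ann):
        introns = toy_ann.intron_set()
        assert classify_gapped("chr1", "-", [(1200, 1500)], introns) == "structural"


class TestAssembly:
    def test_splice_gap_read_emits_no_chimera(self, tmp_path, toy_ann):
        sam = write_sam_text(tmp_path, sam_line("r1", 0, 1151, 60, "50M300N50M"))
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["splice_gapped_discarded"] == 1
        assert res.counts["chimeras"] == 0

    def test_structural_gap_in_one_gene_is_intra(self, tmp_path, toy_ann):
        # gap (1150, 1600) is not an annotated intron
        sam = write_sam_text(tmp_path, sam_line("r1", 0, 1101, 60, "50M450N50M"))
        res = extract_chimeras(sam, toy_ann)
        (c,) = res.chimeras
        assert c.origin == "retained_gap"
        assert c.scope == SCOPE_INTRA
        assert (c.arm5.start, c.arm5.end) == (1100, 1150)
        assert (c.arm3.start, c.arm3.end) == (1600, 1650)

    def test_minus_strand_gapped_read_orders_arms_by_read_direction(
        self, tmp_path, toy_ann
    ):
        sam = write_sam_text(tmp_path, sam_line("r1", 16, 3201, 60, "50M250N50M"))
        res = extract_chimeras(sam, toy_ann)
        (c,) = res.chimeras
        assert c.arm5.start > c.arm3.start  # 5' arm is genomically rightmost on -

    def test_chimera_across_genes_is_inter(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 0, 1001, 60, "30M", "\tSA:Z:chr1,5001,+,30M,60,0;")
            + sam_line("r1", 2048, 5001, 60, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        (c,) = res.chimeras
        assert c.origin == "chimeric_alignment"
        assert (c.gene5, c.gene3) == ("GA", "GC")
        assert c.scope == SCOPE_INTER

    def test_arm_outside_any_gene_is_unassigned(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 0, 1001, 60, "30M", "\tSA:Z:chr1,9001,+,30M,60,0;")
            + sam_line("r1", 2048, 9001, 60, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        assert res.chimeras[0].scope == "unassigned"

    def test_three_segment_read_skipped_with_warning(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 0, 1001, 60, "30M")
            + sam_line("r1", 2048, 2001, 60, "30M")
            + sam_line("r1", 2048, 5001, 60, "30M")
        )
        sam = write_sam_text(tmp_path, body)
        with pytest.warns(UserWarning, match="skipped"):
            res = extract_chimeras(sam, toy_ann)
        assert res.counts["multi_segment_skipped"] == 1


class TestPairedEnd:
    def test_same_contig_mates_merge_into_one_fragment(self, tmp_path, toy_ann):
        body = (
            sam_line("r1", 1 | 64, 1001, 60, "40M")
            + sam_line("r1", 1 | 128, 1031, 60, "40M")  # overlapping mates
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        assert res.counts["nonchimeric"] == 1
        assert res.counts["chimeras"] == 0

    def test_distant_mates_form_structural_chimera(self, tmp_path, toy_ann):
        # mates within one gene, 900 bp apart, non-intronic gap -> intra chimera
        body = (
            sam_line("r1", 1 | 64, 1001, 60, "40M")
            + sam_line("r1", 1 | 128, 2101, 60, "40M")
        )
        sam = write_sam_text(tmp_path, body)
        res = extract_chimeras(sam, toy_ann)
        (c,) = res.chimeras
        assert c.origin == "retained_gap"
        assert c.scope == SCOPE_INTRA


def test_extraction_matches_truth_on_simulated_data(tmp_path):
    """Precision = recall = 1 against the simulator ground truth."""
    _, _, truth, res = simulate_bundle(
        tmp_path, seed=13, n_duplexes=10, n_support=5,
        n_chimeric_reads=500, duplicate_rate=0.15, low_mapq_rate=0.08,
    )
    expected = set(truth[truth.mechanism.isin(CHIMERA_MECHANISMS)].read_id)
    got = {c.read_id for c in res.chimeras}
    assert got == expected
    # conservation: scope labels partition the chimera set
    assert (
        res.counts["intra"] + res.counts["inter"] + res.counts["unassigned"]
        == res.counts["chimeras"]
    )


def test_chimera_tsv_round_trip(tmp_path, toy_ann):
    body = (
        sam_line("r1", 0, 1001, 60, "30M", "\tSA:Z:chr1,5001,+,30M,60,0;")
        + sam_line("r1", 2048, 5001, 60, "30M", "\tSA:Z:chr1,1001,+,30M,60,0;")
    )
    sam = write_sam_text(tmp_path, body)
    res = extract_chimeras(sam, toy_ann)
    p = tmp_path / "c.tsv"
    chimeras_to_tsv(res.chimeras, str(p))
    back = read_chimeras_tsv(str(p))
    assert back == res.chimeras
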